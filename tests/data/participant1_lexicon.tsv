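word	word_class	imageable	use_determiner	audio_form
Jump	verb	true
Peel	verb	true
Froggy	noun	true
Dog	noun	true
Keepy Uppy	fixed_expression	true
Mickey Mouse	proper_noun	true
Shapes	noun	true
Letters	noun	true
Slide	noun	true
Swing	noun	true
Orange	noun	true
Banana	noun	true
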
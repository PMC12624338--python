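word	word_class	imageable	use_determiner	audio_form
Jackpot	proper_noun	true	true
Plinko	proper_noun	true
Mom	proper_noun	true
Dad	proper_noun	true
Alex Trebek	proper_noun	true
Ken Jennings	proper_noun	true
Daniel Tiger	proper_noun	true
School	noun	true
Boy	noun	true
Neighborhood	noun	true
Jeopardy	proper_noun	true
Wheel of Fortune	proper_noun	true
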
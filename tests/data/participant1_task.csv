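trial_number,trial_type,left_image,right_image,audio_script
1,Carrier 1,Jump,Peel,Find jump
2,Carrier 1,Froggy,Dog,Find the dog
3,Carrier 1,Keepy Uppy,Mickey Mouse,Find Mickey Mouse
4,Carrier 1,Shapes,Letters,Find the shapes
5,Carrier 1,Slide,Swing,Find the swing
6,Carrier 1,Jump,Peel,Find peel
7,Carrier 1,Froggy,Dog,Find the froggy
8,Carrier 1,Shapes,Letters,Find the letters
9,Carrier 1,Slide,Swing,Find the slide
10,Carrier 1,Orange,Banana,Find the orange
11,Carrier 1,Mickey Mouse,Keepy Uppy,Find keepy uppy
12,Carrier 1,Banana,Orange,Find the banana
13,Carrier 2,Letters,Shapes,Look at the shapes
14,Carrier 2,Jump,Peel,Look at jump
15,Carrier 2,Banana,Orange,Look at the banana
16,Carrier 2,Dog,Froggy,Look at the froggy
17,Carrier 2,Keepy Uppy,Mickey Mouse,Look at Mickey Mouse
18,Carrier 2,Orange,Banana,Look at the orange
19,Carrier 2,Slide,Swing,Look at the swing
20,Carrier 2,Shapes,Letters,Look at the letters
21,Carrier 2,Slide,Swing,Look at the slide
22,Carrier 2,Dog,Froggy,Look at the dog
23,Carrier 2,Keepy Uppy,Mickey Mouse,Look at keepy uppy
24,Carrier 2,Jump,Peel,Look at peel
25,Single word,Mickey Mouse,Keepy Uppy,Look keepy uppy
26,Single word,Froggy,Dog,Ooh froggy
27,Single word,Banana,Orange,Ooh banana
28,Single word,Peel,Jump,Ooh jump
29,Single word,Orange,Banana,Look orange
30,Single word,Froggy,Dog,Look dog
31,Single word,Mickey Mouse,Keepy Uppy,Ooh Mickey Mouse
32,Single word,Shapes,Letters,Ooh letters
33,Single word,Jump,Peel,Look peel
34,Single word,Swing,Slide,Look swing
35,Single word,Shapes,Letters,Look shapes
36,Single word,Swing,Slide,Ooh slide
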
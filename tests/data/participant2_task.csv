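trial_number,trial_type,left_image,right_image,audio_script
1,Carrier 1,Plinko,Jackpot,Find the Jackpot
2,Carrier 1,Mom,Dad,Find Mom
3,Carrier 1,Alex Trebek,Ken Jennings,Find Alex Trebek
4,Carrier 1,Neighborhood,Boy,Find the boy
5,Carrier 1,Daniel Tiger,School,Find Daniel Tiger
6,Carrier 1,Jackpot,Plinko,Find Plinko
7,Carrier 1,Ken Jennings,Alex Trebek,find Ken Jennings
8,Carrier 1,Mom,Dad,Find Dad
9,Carrier 1,School,Daniel Tiger,Find the school
10,Carrier 1,Jeopardy,Wheel of Fortune,Find Wheel of Fortune
11,Carrier 1,Wheel of Fortune,Jeopardy,Find Jeopardy
12,Carrier 1,Boy,Neighborhood,Find the neighborhood
13,Carrier 2,Jeopardy,Wheel of Fortune,Look at Jeopardy
14,Carrier 2,School,Daniel Tiger,Look at Daniel Tiger
15,Carrier 2,Plinko,Jackpot,Look at Plinko
16,Carrier 2,Daniel Tiger,School,Look at the school
17,Carrier 2,Ken Jennings,Alex Trebek,Look at Alex Trebek
18,Carrier 2,Boy,Neighborhood,Look at the boy
19,Carrier 2,Wheel of Fortune,Jeopardy,Look at Wheel of Fortune
20,Carrier 2,Alex Trebek,Ken Jennings,Look at Ken Jennings
21,Carrier 2,Neighborhood,Boy,Look at the neighborhood
22,Carrier 2,Mom,Dad,Look at Dad
23,Carrier 2,Jackpot,Plinko,Look at the Jackpot
24,Carrier 2,Mom,Dad,Look at Mom
25,Single word,Boy,Neighborhood,Look neighborhood
26,Single word,Mom,Dad,Ooh Mom
27,Single word,Alex Trebek,Ken Jennings,Ooh Alex Trebek
28,Single word,Daniel Tiger,School,Ooh school
29,Single word,Wheel of Fortune,Jeopardy,Look Wheel of Fortune
30,Single word,School,Daniel Tiger,Look Daniel Tiger
31,Single word,Jackpot,Plinko,Ooh Jackpot
32,Single word,Alex Trebek,Ken Jennings,Ooh Ken Jennings
33,Single word,Neighborhood,Boy,Look boy
34,Single word,Jeopardy,Wheel of Fortune,Look Jeopardy
35,Single word,Plinko,Jackpot,Ooh Plinko
36,Single word,Mom,Dad,Look Dad
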
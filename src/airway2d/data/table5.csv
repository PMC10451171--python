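subject_id,h_t,h1,h2,l1_px,l2_px,l1_mm,l2_mm
1,701,685,737,16,36,3.52,7.91
2,642,633,649,9,7,1.98,1.54
3,612,668,576,56,36,12.31,7.91
4,547,551,541,4,6,0.88,1.32
5,597,599,598,2,1,0.44,0.22
6,589,601,574,12,15,2.64,3.3
7,587,583,583,4,4,0.88,0.88
8,640,645,634,5,6,1.1,1.32
9,742,763,726,21,16,4.62,3.52
10,662,660,651,2,11,0.44,2.42
11,550,559,537,9,13,1.98,2.86
12,615,629,604,14,11,3.08,2.42
13,640,640,637,0,3,0,0.66
14,590,601,575,11,15,2.42,3.3
15,571,569,579,2,8,0.44,1.76
16,578,583,576,5,2,1.1,0.44
17,633,628,630,5,3,1.1,0.66
18,569,568,557,1,12,0.22,2.64
19,558,563,547,5,11,1.1,2.42
20,645,658,633,13,12,2.86,2.64
21,675,663,691,12,16,2.64,3.52
22,581,571,573,10,8,2.2,1.76
23,740,717,771,23,31,5.05,6.81
24,631,625,620,6,11,1.32,2.42
25,632,629,622,3,10,0.66,2.2
26,630,639,613,9,17,1.98,3.74
27,677,679,667,2,10,0.44,2.2
28,626,626,637,0,11,0,2.42
29,621,613,625,8,4,1.76,0.88
30,546,531,562,15,16,3.3,3.52
31,596,599,596,3,0,0.66,0
32,570,565,556,5,14,1.1,3.08
33,602,596,600,6,2,1.32,0.44
34,683,679,676,4,7,0.88,1.54
35,677,677,670,0,7,0,1.54
36,698,699,696,1,2,0.22,0.44
37,659,630,704,29,45,6.37,9.89
38,661,673,644,12,17,2.64,3.74
39,586,581,587,5,1,1.1,0.22
40,646,651,649,5,3,1.1,0.66
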
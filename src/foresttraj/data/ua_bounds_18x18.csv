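k,ua_min,ua_max
0,0,0
1,3,8
2,6,16
3,7,24
4,9,32
5,10,40
6,11,48
7,13,56
8,13,64
9,14,72
10,15,80
11,17,88
12,17,96
13,17,104
14,18,112
15,19,120
16,21,128
17,21,136
18,21,144
19,21,152
20,22,160
21,23,168
22,25,176
23,25,184
24,25,192
25,25,200
26,25,208
27,26,216
28,27,224
29,29,232
30,29,240
31,29,248
32,29,256
33,29,264
34,29,272
35,30,280
36,31,288
37,33,296
38,33,304
39,33,312
40,33,320
41,33,328
42,33,336
43,33,344
44,34,352
45,35,360
46,37,368
47,37,376
48,37,384
49,37,392
50,37,400
51,37,408
52,37,416
53,37,424
54,38,432
55,39,440
56,41,448
57,41,456
58,41,464
59,41,472
60,41,480
61,41,488
62,41,496
63,41,504
64,41,512
65,42,518
66,43,524
67,45,530
68,45,536
69,45,542
70,45,548
71,45,554
72,45,560
73,45,566
74,45,572
75,45,578
76,45,584
77,46,590
78,47,596
79,49,602
80,49,607
81,49,611
82,49,615
83,49,619
84,49,623
85,49,627
86,49,631
87,49,635
88,49,639
89,49,643
90,50,647
91,51,651
92,53,655
93,53,659
94,53,663
95,53,667
96,53,671
97,53,675
98,53,679
99,53,683
100,53,687
101,53,691
102,53,695
103,53,699
104,54,703
105,55,707
106,57,711
107,57,715
108,57,719
109,57,723
110,57,727
111,57,731
112,57,735
113,57,739
114,57,743
115,57,747
116,57,751
117,57,755
118,57,759
119,58,763
120,59,767
121,61,771
122,61,775
123,61,779
124,61,783
125,61,787
126,61,791
127,61,795
128,61,799
129,61,803
130,61,806
131,61,809
132,61,812
133,61,815
134,61,818
135,62,821
136,63,824
137,65,827
138,65,830
139,65,833
140,65,836
141,65,839
142,65,842
143,65,845
144,65,848
145,65,851
146,65,854
147,65,857
148,65,860
149,65,863
150,65,866
151,65,869
152,66,872
153,67,874
154,67,875
155,66,876
156,66,876
157,66,876
158,65,876
159,65,876
160,65,876
161,65,875
162,64,874
163,65,875
164,65,876
165,65,876
166,65,876
167,66,876
168,66,876
169,66,876
170,67,875
171,67,874
172,66,872
173,65,869
174,65,866
175,65,863
176,65,860
177,65,857
178,65,854
179,65,851
180,65,848
181,65,845
182,65,842
183,65,839
184,65,836
185,65,833
186,65,830
187,65,827
188,63,824
189,62,821
190,61,818
191,61,815
192,61,812
193,61,809
194,61,806
195,61,803
196,61,799
197,61,795
198,61,791
199,61,787
200,61,783
201,61,779
202,61,775
203,61,771
204,59,767
205,58,763
206,57,759
207,57,755
208,57,751
209,57,747
210,57,743
211,57,739
212,57,735
213,57,731
214,57,727
215,57,723
216,57,719
217,57,715
218,57,711
219,55,707
220,54,703
221,53,699
222,53,695
223,53,691
224,53,687
225,53,683
226,53,679
227,53,675
228,53,671
229,53,667
230,53,663
231,53,659
232,53,655
233,51,651
234,50,647
235,49,643
236,49,639
237,49,635
238,49,631
239,49,627
240,49,623
241,49,619
242,49,615
243,49,611
244,49,607
245,49,602
246,47,596
247,46,590
248,45,584
249,45,578
250,45,572
251,45,566
252,45,560
253,45,554
254,45,548
255,45,542
256,45,536
257,45,530
258,43,524
259,42,518
260,41,512
261,41,504
262,41,496
263,41,488
264,41,480
265,41,472
266,41,464
267,41,456
268,41,448
269,39,440
270,38,432
271,37,424
272,37,416
273,37,408
274,37,400
275,37,392
276,37,384
277,37,376
278,37,368
279,35,360
280,34,352
281,33,344
282,33,336
283,33,328
284,33,320
285,33,312
286,33,304
287,33,296
288,31,288
289,30,280
290,29,272
291,29,264
292,29,256
293,29,248
294,29,240
295,29,232
296,27,224
297,26,216
298,25,208
299,25,200
300,25,192
301,25,184
302,25,176
303,23,168
304,22,160
305,21,152
306,21,144
307,21,136
308,21,128
309,19,120
310,18,112
311,17,104
312,17,96
313,17,88
314,15,80
315,14,72
316,13,64
317,13,56
318,11,48
319,10,40
320,9,32
321,7,24
322,6,16
323,3,8
324,0,0
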
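id,name,type,module,adjacency
1,Acetabulum,bone,Thigh,2 8 20 22 27 28 29 30 31 40 41 44 45 48
2,Adductor femoris,muscle,Thigh,1 22
3,Aponeurosis plantaris,connective_knot,Foot,10 11 12 13 14 23 24 33 50
4,Caudofemoralis,muscle,Hip,22 54
5,Coccygeoiliacus,muscle,Hip,28 54
6,Coccygeosacralis,muscle,Hip,46 54
7,Contrahentium caput longum,muscle,Shank,33 50
8,Cruralis,muscle,Thigh,1 20 21 32
9,Cruroastralagus,muscle,Shank,50 53
10,Digit I,bone,Foot,3 34
11,Digit II,bone,Foot,3 35
12,Digit III,bone,Foot,3 36
13,Digit IV,bone,Foot,3 37
14,Digit V,bone,Foot,3 38
15,Distal tarsal 1,bone,Foot,16 34 35 50
16,Distal tarsal 2-3,bone,Foot,15 23 35 36 37 50
17,Extensor cruris tibialis,muscle,Shank,22 53
18,Extensor digitorum longus,muscle,Foot,35 36 37 53
19,Extensor iliotibialis A,muscle,Hip,21 28
20,Extensor iliotibialis B,muscle,Thigh,1 8 21
21,Fascia latae,connective_knot,Thigh,8 19 20 32
22,Femur,bone,Thigh,1 2 4 17 25 26 29 30 31 32 39 40 41 42 43 49 51
23,Fibulare,bone,Foot,3 16 37 38 39 50 51 53
24,Flexor digitorum communis,muscle,Calf,3 25 26
25,Flexor digitorum communis ot Knot I,connective_knot,Calf,22 24 53
26,Flexor digitorum communis ot Knot II,connective_knot,Calf,22 24 53
27,Gracilis major et minor,muscle,Shank,1 53
28,Iliac shaft,bone,Hip,1 5 19 42 43 46
29,Iliofemoralis,muscle,Thigh,1 22
30,Ischioflexorius,muscle,Thigh,1 22
31,Ischiotrochantericus B,muscle,Thigh,1 22
32,Knee Knot,connective_knot,Thigh,8 21 22 49 53
33,Ligamentum calcanei,connective_knot,Shank,3 7 53
34,Metatarsal I,bone,Foot,10 15
35,Metatarsal II,bone,Foot,11 15 16 18
36,Metatarsal III,bone,Foot,12 16 18
37,Metatarsal IV,bone,Foot,13 16 18 23
38,Metatarsal V,bone,Foot,14 23
39,Peroneus,muscle,Foot,22 23
40,Puboischiofemoralis externus A,muscle,Thigh,1 22
41,Puboischiofemoralis externus B,muscle,Thigh,1 22
42,Puboischiofemoralis internus A,muscle,Hip,22 28
43,Puboischiofemoralis internus B,muscle,Hip,22 28
44,Pubotibialis A,muscle,Shank,1 53
45,Pubotibialis B,muscle,Shank,1 53
46,Sacral vertebra,bone,Hip,6 28 54
47,Tarsalis anticus,muscle,Shank,50 53
48,Tenuissimus,muscle,Thigh,1 49
49,Tenuissimus it Knot,connective_knot,Thigh,22 32 48 53
50,Tibiale,bone,Shank,3 7 9 15 16 23 47 51 52 53
51,Tibialis anticus,muscle,Shank,22 23 50
52,Tibialis anticus brevis,muscle,Shank,50 53
53,Tibiofibula,bone,Shank,9 17 18 23 25 26 27 32 33 44 45 47 49 50 52
54,Urostyle,bone,Hip,4 5 6 46
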
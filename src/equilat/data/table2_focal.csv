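horse_id,sex,sequence
A,gelding,RRRRLRRRRRLRLRRRRRLRRLRLRRLL
B,gelding,RRRRLRLRRRLRRRRRRL
C,gelding,LRLLLLLLLLLRLRLLLRLLL
D,gelding,LRRRRRRLLLLLRR
E,gelding,RRRLLRRR
F,gelding,LLLLLLL
G,gelding,LLLLLLR
H,gelding,RLLRRRRRR
I,gelding,LLRLLRLLLRLLLLRLR
J,gelding,LLRLLLLLLLLLRLRL
K,gelding,LRRLRLLL
L,mare,LLLLRLLLLRRLLLLLRLRRRLLLRLLRRLL
M,mare,RRRLRRRLLRLL
N,mare,RLRRLLRRLLLLRRLRRRLL
O,mare,RLLLLLLLLLLR
P,mare,RRLRRLRRRLRRLR
Q,mare,LLRLRLRLLLRLLLLRLRRRLRLRRL
R,mare,RRRLRRRLLLLLRLLL
S,mare,RLRRRLLRRL
T,mare,RLLRLLRLRLRRRRLRR
U,mare,LLLLLL
V,mare,LLLRLRRLRRRRL
W,mare,RLRRRRRRLRR
X,mare,RLLRLRRRRLRRRLRLL
Y,mare,LRRRRLLRRRRLRR
Z,mare,LLLLRL
AA,mare,RRRRRLRLLLRLRL
AB,mare,LLRLRLLLR
AC,mare,LLLLLLLL
AD,mare,LLLLLLR
AE,mare,RRLRLRRRR
AF,mare,LLLLRLLRLL
AG,mare,LRLRRLRR
AH,stallion,RRLRLRRRLRLRLLLLLLR
AI,stallion,RLLLLRRRRRRL
AJ,stallion,LLRLRRLRLLLR
AK,stallion,RLLLLL
AL,stallion,RLRRRLR
AM,stallion,LRRLLRRLR
AN,stallion,RRLRR
AO,stallion,RRLRRRL
AP,stallion,LLRLLLLLLRLLLLLLLLRLLLLRLRLLRRLLLLLLLLRRRLLRLRL
AQ,stallion,RLRRRRLLLLLLLLLLLRLLR
AR,stallion,LRRLRRRRR
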
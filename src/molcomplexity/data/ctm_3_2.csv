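#meta states=3 symbols=2 max_steps=107 machines_total=7529536 machines_halted=4294368 method=exhaustive
0,1.997239785311
00,3.313209032084
000,6.481345298085
0000,10.013034456695
00000,13.333574677458
000000,18.034014395599
000001,18.449051894878
0000010,21.034014395599
00001,14.375802912847
000010,19.034014395599
000011,20.034014395599
0000110,21.034014395599
0001,10.890631181609
00010,14.319768877933
000100,18.712086300712
00011,15.479425543922
000110,20.034014395599
001,6.538034487081
0010,10.483267610216
00100,14.419304551484
001000,18.712086300712
001001,19.034014395599
00101,15.390158205825
001010,19.034014395599
0011,11.603561843934
00110,14.252654682075
001100,20.034014395599
001101,20.034014395599
00111,15.479425543922
001110,21.034014395599
001111,20.034014395599
01,3.313209032084
010,6.647612971958
0100,10.483267610216
01000,14.319768877933
010000,19.034014395599
0100000,21.034014395599
010001,20.034014395599
01001,14.641696972820
010010,20.034014395599
010011,20.034014395599
0101,10.584865750224
01010,14.542161299270
010100,19.034014395599
0101010,20.034014395599
01011,15.390158205825
010110,19.449051894878
0101110,21.034014395599
011,6.538034487081
0110,10.935982312639
01100,14.252654682075
011000,20.034014395599
0110000,21.034014395599
01101,14.641696972820
011010,19.449051894878
011011,19.034014395599
0111,10.890631181609
01110,15.079818085212
011100,21.034014395599
011101,20.034014395599
0111010,21.034014395599
01111,14.375802912847
011110,20.034014395599
011111,18.449051894878
1,1.997239785311
10,3.313209032084
100,6.538034487081
1000,10.890631181609
10000,14.375802912847
100000,18.449051894878
100001,20.034014395599
10001,15.079818085212
100010,20.034014395599
1000101,21.034014395599
100011,21.034014395599
1001,10.935982312639
10010,14.641696972820
100100,19.034014395599
100101,19.449051894878
10011,14.252654682075
100111,20.034014395599
1001111,21.034014395599
101,6.647612971958
1010,10.584865750224
10100,15.390158205825
1010001,21.034014395599
101001,19.449051894878
10101,14.542161299270
1010101,20.034014395599
101011,19.034014395599
1011,10.483267610216
10110,14.641696972820
101100,20.034014395599
101101,20.034014395599
10111,14.319768877933
101110,20.034014395599
101111,19.034014395599
1011111,21.034014395599
11,3.313209032084
110,6.538034487081
1100,11.603561843934
11000,15.479425543922
110000,20.034014395599
110001,21.034014395599
11001,14.252654682075
110010,20.034014395599
110011,20.034014395599
1101,10.483267610216
11010,15.390158205825
110101,19.034014395599
11011,14.419304551484
110110,19.034014395599
110111,18.712086300712
111,6.481345298085
1110,10.890631181609
11100,15.479425543922
111001,20.034014395599
11101,14.319768877933
111011,18.712086300712
1111,10.013034456695
11110,14.375802912847
111100,20.034014395599
1111001,21.034014395599
111101,19.034014395599
11111,13.333574677458
111110,18.449051894878
1111101,21.034014395599
111111,18.034014395599
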
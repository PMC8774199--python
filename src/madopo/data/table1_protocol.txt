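#01	cathode=C1:1	anode=C2:0.333333333333,C3:0.333333333333,C4:0.333333333333	amplitude_mA=3	family=vertical
#02	cathode=C2:0.333333333333,C3:0.333333333333,C4:0.333333333333	anode=C5:0.333333333333,C6:0.333333333333,C7:0.333333333333	amplitude_mA=3	family=vertical
#03	cathode=C5:0.333333333333,C6:0.333333333333,C7:0.333333333333	anode=C8:1	amplitude_mA=3	family=vertical
#04	cathode=C1:1	anode=C5:0.333333333333,C6:0.333333333333,C7:0.333333333333	amplitude_mA=3	family=vertical
#05	cathode=C2:0.333333333333,C3:0.333333333333,C4:0.333333333333	anode=C8:1	amplitude_mA=3	family=vertical
#06	cathode=C1:1	anode=C8:1	amplitude_mA=3	family=vertical
#07	cathode=C1:1	anode=C2:1	amplitude_mA=3	family=diagonal
#08	cathode=C1:1	anode=C3:1	amplitude_mA=3	family=diagonal
#09	cathode=C1:1	anode=C4:1	amplitude_mA=3	family=diagonal
#10	cathode=C5:1	anode=C8:1	amplitude_mA=3	family=diagonal
#11	cathode=C6:1	anode=C8:1	amplitude_mA=3	family=diagonal
#12	cathode=C7:1	anode=C8:1	amplitude_mA=3	family=diagonal
#13	cathode=C2:1	anode=C3:1	amplitude_mA=3	family=horizontal
#14	cathode=C3:1	anode=C4:1	amplitude_mA=3	family=horizontal
#15	cathode=C4:1	anode=C2:1	amplitude_mA=3	family=horizontal
#16	cathode=C5:1	anode=C6:1	amplitude_mA=3	family=horizontal
#17	cathode=C6:1	anode=C7:1	amplitude_mA=3	family=horizontal
#18	cathode=C7:1	anode=C5:1	amplitude_mA=3	family=horizontal
#19	cathode=C2:0.5,C3:0.5	anode=C4:1	amplitude_mA=3	family=symmetrical
#20	cathode=C3:0.5,C4:0.5	anode=C2:1	amplitude_mA=3	family=symmetrical
#21	cathode=C4:0.5,C2:0.5	anode=C3:1	amplitude_mA=3	family=symmetrical
#22	cathode=C5:0.5,C6:0.5	anode=C7:1	amplitude_mA=3	family=symmetrical
#23	cathode=C6:0.5,C7:0.5	anode=C5:1	amplitude_mA=3	family=symmetrical
#24	cathode=C7:0.5,C5:0.5	anode=C6:1	amplitude_mA=3	family=symmetrical
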
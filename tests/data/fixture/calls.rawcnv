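chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	NEL_F0001	startsnp=p400500	endsnp=p430500
chr1:922500-994500	numsnp=25	length=72001	state2,cn=1	NEL_F0001	startsnp=p922500	endsnp=p994500
chr2:298500-319500	numsnp=8	length=21001	state5,cn=3	NEL_F0001	startsnp=p298500	endsnp=p319500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_F0001	startsnp=p1498500	endsnp=p1552500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	NEL_F0002	startsnp=p400500	endsnp=p430500
chr1:913500-985500	numsnp=25	length=72001	state2,cn=1	NEL_F0002	startsnp=p913500	endsnp=p985500
chr1:1582500-1582500	numsnp=1	length=1	state2,cn=1	NEL_F0002	startsnp=p1582500	endsnp=p1582500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	NEL_F0003	startsnp=p400500	endsnp=p430500
chr1:1576500-1582500	numsnp=3	length=6001	state2,cn=1	NEL_F0003	startsnp=p1576500	endsnp=p1582500
chr2:298500-319500	numsnp=8	length=21001	state5,cn=3	NEL_F0003	startsnp=p298500	endsnp=p319500
chr2:1360500-1369500	numsnp=4	length=9001	state5,cn=3	NEL_F0003	startsnp=p1360500	endsnp=p1369500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	NEL_F0004	startsnp=p400500	endsnp=p430500
chr1:919500-982500	numsnp=22	length=63001	state2,cn=1	NEL_F0004	startsnp=p919500	endsnp=p982500
chr1:1582500-1582500	numsnp=1	length=1	state2,cn=1	NEL_F0004	startsnp=p1582500	endsnp=p1582500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_F0004	startsnp=p1498500	endsnp=p1552500
chr2:1693500-1786500	numsnp=32	length=93001	state2,cn=1	NEL_F0004	startsnp=p1693500	endsnp=p1786500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	NEL_F0005	startsnp=p400500	endsnp=p430500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_F0005	startsnp=p1498500	endsnp=p1552500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	NEL_F0006	startsnp=p400500	endsnp=p430500
chr1:1582500-1585500	numsnp=2	length=3001	state2,cn=1	NEL_F0006	startsnp=p1582500	endsnp=p1585500
chr2:298500-319500	numsnp=8	length=21001	state5,cn=3	NEL_F0006	startsnp=p298500	endsnp=p319500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_F0006	startsnp=p1498500	endsnp=p1552500
chr2:1702500-1792500	numsnp=31	length=90001	state2,cn=1	NEL_F0006	startsnp=p1702500	endsnp=p1792500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	NEL_F0007	startsnp=p400500	endsnp=p430500
chr1:1579500-1582500	numsnp=2	length=3001	state2,cn=1	NEL_F0007	startsnp=p1579500	endsnp=p1582500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_F0007	startsnp=p1498500	endsnp=p1552500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	NEL_F0008	startsnp=p400500	endsnp=p430500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_F0008	startsnp=p1498500	endsnp=p1552500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	NEL_F0009	startsnp=p400500	endsnp=p430500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_F0009	startsnp=p1498500	endsnp=p1552500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	NEL_F0010	startsnp=p400500	endsnp=p430500
chr1:1582500-1582500	numsnp=1	length=1	state2,cn=1	NEL_F0010	startsnp=p1582500	endsnp=p1582500
chr2:298500-319500	numsnp=8	length=21001	state5,cn=3	NEL_F0010	startsnp=p298500	endsnp=p319500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_M0001	startsnp=p1498500	endsnp=p1552500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_M0002	startsnp=p1498500	endsnp=p1552500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_M0004	startsnp=p1498500	endsnp=p1552500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_M0005	startsnp=p1498500	endsnp=p1552500
chr1:913500-985500	numsnp=25	length=72001	state2,cn=1	NEL_M0006	startsnp=p913500	endsnp=p985500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_M0006	startsnp=p1498500	endsnp=p1552500
chr1:1582500-1582500	numsnp=1	length=1	state2,cn=1	NEL_M0007	startsnp=p1582500	endsnp=p1582500
chr1:922500-994500	numsnp=25	length=72001	state2,cn=1	NEL_M0008	startsnp=p922500	endsnp=p994500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_M0008	startsnp=p1498500	endsnp=p1552500
chr1:1582500-1582500	numsnp=1	length=1	state2,cn=1	NEL_M0009	startsnp=p1582500	endsnp=p1582500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	NEL_M0009	startsnp=p1498500	endsnp=p1552500
chr1:919500-994500	numsnp=26	length=75001	state2,cn=1	NEL_M0010	startsnp=p919500	endsnp=p994500
chr2:1882500-1894500	numsnp=5	length=12001	state2,cn=1	NEL_M0010	startsnp=p1882500	endsnp=p1894500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	TAU_F0001	startsnp=p400500	endsnp=p430500
chr2:298500-319500	numsnp=8	length=21001	state5,cn=3	TAU_F0001	startsnp=p298500	endsnp=p319500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	TAU_F0002	startsnp=p400500	endsnp=p430500
chr1:1582500-1582500	numsnp=1	length=1	state2,cn=1	TAU_F0002	startsnp=p1582500	endsnp=p1582500
chr2:298500-319500	numsnp=8	length=21001	state5,cn=3	TAU_F0002	startsnp=p298500	endsnp=p319500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	TAU_F0003	startsnp=p400500	endsnp=p430500
chr1:916500-985500	numsnp=24	length=69001	state2,cn=1	TAU_F0003	startsnp=p916500	endsnp=p985500
chr2:1882500-1885500	numsnp=2	length=3001	state2,cn=1	TAU_F0003	startsnp=p1882500	endsnp=p1885500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	TAU_F0004	startsnp=p400500	endsnp=p430500
chr1:922500-985500	numsnp=22	length=63001	state2,cn=1	TAU_F0004	startsnp=p922500	endsnp=p985500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	TAU_F0005	startsnp=p400500	endsnp=p430500
chr2:298500-319500	numsnp=8	length=21001	state5,cn=3	TAU_F0005	startsnp=p298500	endsnp=p319500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	TAU_F0006	startsnp=p400500	endsnp=p430500
chr2:1696500-1795500	numsnp=34	length=99001	state2,cn=1	TAU_F0006	startsnp=p1696500	endsnp=p1795500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	TAU_F0007	startsnp=p400500	endsnp=p430500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	TAU_F0008	startsnp=p400500	endsnp=p430500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	TAU_F0009	startsnp=p400500	endsnp=p430500
chr2:298500-319500	numsnp=8	length=21001	state5,cn=3	TAU_F0009	startsnp=p298500	endsnp=p319500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	TAU_F0009	startsnp=p1498500	endsnp=p1552500
chr1:400500-430500	numsnp=11	length=30001	state1,cn=0	TAU_F0010	startsnp=p400500	endsnp=p430500
chr1:910500-988500	numsnp=27	length=78001	state2,cn=1	TAU_M0001	startsnp=p910500	endsnp=p988500
chr1:1507500-1519500	numsnp=5	length=12001	state2,cn=1	TAU_M0002	startsnp=p1507500	endsnp=p1519500
chr2:1702500-1798500	numsnp=33	length=96001	state2,cn=1	TAU_M0002	startsnp=p1702500	endsnp=p1798500
chr1:1504500-1522500	numsnp=7	length=18001	state2,cn=1	TAU_M0004	startsnp=p1504500	endsnp=p1522500
chr1:922500-988500	numsnp=23	length=66001	state2,cn=1	TAU_M0005	startsnp=p922500	endsnp=p988500
chr1:913500-985500	numsnp=25	length=72001	state2,cn=1	TAU_M0006	startsnp=p913500	endsnp=p985500
chr1:1504500-1519500	numsnp=6	length=15001	state2,cn=1	TAU_M0006	startsnp=p1504500	endsnp=p1519500
chr1:1582500-1588500	numsnp=3	length=6001	state2,cn=1	TAU_M0006	startsnp=p1582500	endsnp=p1588500
chr1:1513500-1516500	numsnp=2	length=3001	state2,cn=1	TAU_M0007	startsnp=p1513500	endsnp=p1516500
chr1:1582500-1582500	numsnp=1	length=1	state2,cn=1	TAU_M0007	startsnp=p1582500	endsnp=p1582500
chr2:1690500-1795500	numsnp=36	length=105001	state2,cn=1	TAU_M0007	startsnp=p1690500	endsnp=p1795500
chr1:1579500-1585500	numsnp=3	length=6001	state2,cn=1	TAU_M0008	startsnp=p1579500	endsnp=p1585500
chr2:1498500-1552500	numsnp=19	length=54001	state2,cn=1	TAU_M0009	startsnp=p1498500	endsnp=p1552500
chr1:922500-994500	numsnp=25	length=72001	state2,cn=1	TAU_M0010	startsnp=p922500	endsnp=p994500
chr1:1582500-1591500	numsnp=4	length=9001	state2,cn=1	TAU_M0010	startsnp=p1582500	endsnp=p1591500
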
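# Human mitotic kinetochore: molecular geometry (mass kDa -> sphere radius Å,
# constant density calibrated to histone H3).  Types below the marker comment
# are auxiliary beads of the bundled fixture (synthetic choices, no printed
# radius): core histones, the inert second CenpA copy of the CenpA
# nucleosome, Ska subunits and the tubulin bead of the microtubule template.
type	mass_kDa	radius_A
CenpA	16.00	15.33
CenpB	65.00	24.46
CenpC	107.00	28.88
CenpI	87.00	26.95
CenpK	31.50	19.21
CenpM	20.00	16.51
CenpN	39.50	20.71
CenpO	34.00	19.00
CenpP	33.00	19.51
CenpQ	30.50	19.01
CenpR	20.00	16.51
CenpS	16.00	15.33
CenpT	60.50	23.88
CenpU	47.50	22.03
CenpW	10.00	13.10
CenpX	9.00	12.65
H3	15.00	15.00
Dsn1	40.00	20.80
Mis12	24.00	17.55
Nnf1	23.50	17.42
Nsl1	32.00	19.31
Hec1	74.00	25.54
Nuf2	54.00	22.99
Spc24	22.50	17.17
Spc25	26.00	18.02
Knl1	265.00	39.07
Apc1	216.50	36.53
Apc2	94.00	27.66
Apc3	92.00	27.46
Apc4	92.00	27.46
Apc5	85.00	26.75
Apc6	71.50	25.25
Apc7	67.00	24.71
Apc8	69.00	24.95
Apc10	21.00	16.78
Apc11	10.00	13.11
Apc12	10.00	13.11
Apc13	8.50	12.41
Cdc20	55.00	23.13
Mad1	83.00	26.53
Mad2	23.50	17.42
Bub1	122.00	30.17
BubR1	120.00	30.00
Bub3	37.00	20.27
Mps1	97.00	27.95
Zwint	31.00	19.11
Zwilch	67.00	24.71
Zw10	89.00	27.16
Rod1	250.00	38.32
# auxiliary fixture beads (computed radii)
H4	11.40
H2A	14.00
H2B	13.90
CenpA2	16.00
Ska1	29.50
Ska2	14.00
Ska3	46.00
Tubulin	110.00
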
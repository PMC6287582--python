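* Minimal CHARMM-format nonbonded parameter table bundled with rinmd.
* Covers the atom types used by the built-in residue template table so that
* static PDB input can be analysed without an external force-field file.
* Columns: type  ignored  epsilon(kcal/mol, negative by convention)  Rmin/2(A)
*

NONBONDED nbxmod 5 atom cdiel shift vatom vdistance vswitch

C      0.0  -0.110000  2.0000
CA     0.0  -0.070000  1.9924
CC     0.0  -0.070000  2.0000
CY     0.0  -0.073000  1.9900
CPT    0.0  -0.099000  1.8600
CPH1   0.0  -0.050000  1.8000
CPH2   0.0  -0.050000  1.8000
CP1    0.0  -0.020000  2.2750
CP2    0.0  -0.055000  2.1750
CP3    0.0  -0.055000  2.1750
CT1    0.0  -0.032000  2.0000
CT2    0.0  -0.056000  2.0100
CT2A   0.0  -0.056000  2.0100
CT3    0.0  -0.078000  2.0400
N      0.0  -0.200000  1.8500
NC2    0.0  -0.200000  1.8500
NH1    0.0  -0.200000  1.8500
NH2    0.0  -0.200000  1.8500
NH3    0.0  -0.200000  1.8500
NR1    0.0  -0.200000  1.8500
NR2    0.0  -0.200000  1.8500
NR3    0.0  -0.200000  1.8500
NY     0.0  -0.200000  1.8500
O      0.0  -0.120000  1.7000
OC     0.0  -0.120000  1.7000
OH1    0.0  -0.152100  1.7700
S      0.0  -0.450000  2.0000
H      0.0  -0.046000  0.2245
HC     0.0  -0.046000  0.2245
HS     0.0  -0.100000  0.4500
HB1    0.0  -0.022000  1.3200
HB2    0.0  -0.028000  1.3400
HA1    0.0  -0.045000  1.3400
HA2    0.0  -0.034000  1.3400
HA3    0.0  -0.024000  1.3400
HP     0.0  -0.030000  1.3582
HR1    0.0  -0.046000  0.9000
HR2    0.0  -0.046000  0.7000
HR3    0.0  -0.007800  1.4680

END
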
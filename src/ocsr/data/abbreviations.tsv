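# Superatom abbreviation dictionary: ABBREV<TAB>SMILES with the attachment
# point marked by *.  Users may extend or override this table.
Me	*C
Et	*CC
Pr	*CCC
iPr	*C(C)C
nBu	*CCCC
tBu	*C(C)(C)C
Ph	*C1=CC=CC=C1
Bn	*CC1=CC=CC=C1
Ac	*C(=O)C
Bz	*C(=O)C1=CC=CC=C1
OMe	*OC
MeO	*OC
OEt	*OCC
EtO	*OCC
OAc	*OC(=O)C
AcO	*OC(=O)C
OBn	*OCC1=CC=CC=C1
NO2	*[N+](=O)[O-]
O2N	*[N+](=O)[O-]
CN	*C#N
NC	*C#N
CF3	*C(F)(F)F
F3C	*C(F)(F)F
CCl3	*C(Cl)(Cl)Cl
COOH	*C(=O)O
HOOC	*C(=O)O
CO2H	*C(=O)O
CO2Me	*C(=O)OC
COOMe	*C(=O)OC
CHO	*C=O
OHC	*C=O
SO3H	*S(=O)(=O)O
SMe	*SC
MeS	*SC
NMe2	*N(C)C
NHMe	*NC
NHAc	*NC(=O)C
OTs	*OS(=O)(=O)C1=CC=C(C)C=C1
OTos	*OS(=O)(=O)C1=CC=C(C)C=C1
Ms	*S(=O)(=O)C
Boc	*C(=O)OC(C)(C)C
Cbz	*C(=O)OCC1=CC=CC=C1
TMS	*[Si](C)(C)C
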
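"""Small published reference inputs used in worked examples and tests."""

#: The twelve myosin neo-N-terminal peptides reported by TAILS in 48 hpf
#: zebrafish embryos after metalloproteinase inhibition, with their
#: normalized heavy:light ratios.  Four carry Ile/Leu/Val at P1',
#: characteristic of gelatinase A cleavage.
MYOSIN_TAILS_TSV = """\
peptide\tprotein_description\thl_ratio
DLEESTLQHEATAAALR\tmyosin heavy chain, fast skeletal muscle\t8.3856
IEELEEELEAER\tmyosin heavy chain, fast skeletal muscle\t7.6228
ELETEIEAEQR\tmyosin heavy chain, fast skeletal muscle\t6.6756
ADLSRELEEISER\tmyosin heavy chain, fast skeletal muscle\t4.6963
VRELESEVEAEQR\tmyosin heavy chain, fast skeletal muscle\t4.4234
TLEDQLSEIKSKNDENLR\tmyosin heavy chain, fast skeletal muscle\t3.4527
VQLELNQVKSEIDR\tmyosin heavy chain, fast skeletal muscle\t3.4453
LEDEEEINAELTAKKR\tmyosin heavy chain, fast skeletal muscle\t3.3276
ELESEVEAEQR\tmyosin heavy chain, fast skeletal muscle\t3.1041
ADIAESQVNKLR\tmyosin heavy chain, fast skeletal muscle\t3.0920
EQFEEEQEAKAELQR\tmyosin heavy chain, fast skeletal muscle\t3.0497
QLEEKEALVSQLTR\tmyosin heavy chain, fast skeletal muscle\t3.0294
"""

#: Expected P1' residues for the table above, in row order.
MYOSIN_TAILS_P1PRIME = (
    "Asp", "Ile", "Glu", "Ala", "Val", "Thr",
    "Val", "Leu", "Glu", "Ala", "Glu", "Gln",
)
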
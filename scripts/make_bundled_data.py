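"""One-off generator for the bundled synthetic reference FASTA files."""
import numpy as np

rng = np.random.default_rng(20150763)
BASES = np.array(list("ACGT"))

def seq(n, gc=0.46):
    p = np.array([(1-gc)/2, gc/2, gc/2, (1-gc)/2])
    return "".join(rng.choice(BASES, size=n, p=p))

def wrap(s, w=70):
    return "\n".join(s[i:i+w] for i in range(0, len(s), w))

# --- repeat library: coded family names, Gypsy-heavy grass-like set
repeats = [
    ("RLG-synfam1", 3000), ("RLG-synfam2", 2500), ("RLG-synfam3", 2000),
    ("RLG-synfam4", 1500), ("RLC-synfam1", 2200), ("RLC-synfam2", 1200),
    ("DTC-synJorge", 2800), ("DTC-synfam2", 1000), ("DTA-synfam1", 800),
    ("RIX-synfam1", 1600), ("RLX-synfam1", 900), ("DTM-synfam1", 700),
]
with open("/root/pkg/src/chromosurvey/_data/synthetic_repeat_library.fa", "w") as fh:
    for name, n in repeats:
        fh.write(f">{name} synthetic repeat element, superfamily={name[:3]}\n{wrap(seq(n, gc=0.48))}\n")

# --- organellar / rRNA decoys (~2 kb each)
decoys = [
    ("chloroplast_decoy", "chloroplast", 2000, 0.37),
    ("mitochondrion_decoy", "mitochondrion", 2000, 0.44),
    ("rrna_decoy", "rRNA", 1800, 0.55),
]
with open("/root/pkg/src/chromosurvey/_data/synthetic_organellar_decoys.fa", "w") as fh:
    for name, kind, n, gc in decoys:
        fh.write(f">{name} kind={kind} synthetic decoy sequence\n{wrap(seq(n, gc))}\n")

# --- mature miRNA library, miRBase-style headers, RNA alphabet
fams = [("miR2118", 5), ("miR167", 2), ("miR169", 2), ("miR399", 2),
        ("miR156", 1), ("miR164", 1), ("miR5048", 1)]
RNA = np.array(list("ACGU"))
with open("/root/pkg/src/chromosurvey/_data/synthetic_mature_mirnas.fa", "w") as fh:
    i = 0
    for fam, k in fams:
        for j in range(k):
            i += 1
            letter = "abcde"[j]
            s = "".join(rng.choice(RNA, size=21))
            fh.write(f">tdi-{fam}{letter} MIMATSYN{i:07d} Triticum dicoccoides {fam}{letter} (synthetic)\n{s}\n")

# --- group-5 inter-model synteny map (mutually colinear chromosome groups)
with open("/root/pkg/src/chromosurvey/_data/group5_synteny_map.tsv", "w") as fh:
    fh.write("group_id\tspecies\tchromosome\n")
    for gid, members in [(1, [("Bd","1"),("Os","3"),("Sb","1")]),
                         (2, [("Bd","4"),("Os","9"),("Sb","2")]),
                         (3, [("Bd","4"),("Os","12"),("Sb","2")])]:
        for sp, ch in members:
            fh.write(f"{gid}\t{sp}\t{ch}\n")
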
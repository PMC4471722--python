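"""Homology-based miRNA discovery with hairpin and MFEI filtering.

Known mature miRNAs are scanned against genomic/assembly sequences with a
bounded mismatch count (both strands); candidate precursor windows around
each hit are folded; and hairpin candidates are accepted when the mature
sits in one arm of a single hairpin, is nearly fully paired in the
miRNA/miRNA* duplex, and the precursor's minimal-folding-free-energy
index (MFEI) exceeds the cutoff separating miRNA precursors from
tRNA/rRNA/mRNA backgrounds:

    MFEI = (−MFE / length × 100) / (GC% )

The folding engine is a pluggable contract (sequence -> dot-bracket
structure + MFE in kcal/mol). The bundled engine is a simplified
pair-energy dynamic program (GC −3.0, AU −2.0, GU −1.0 kcal/mol, −0.5
stacking bonus, +8.0 loop-opening penalty, minimum hairpin loop 3); it
ranks hairpins correctly but its absolute energies are not those of a
full thermodynamic nearest-neighbour model. Externally computed
dot-bracket + MFE output can be supplied instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .seqio import ReadRecord

# ---------------------------------------------------------------------------
# mature library

_FAMILY_RE = re.compile(r"(miR[0-9]+)", re.IGNORECASE)


@dataclass
class MatureMiRNA:
    """A mature miRNA; family is parsed from the miRBase-style name."""

    name: str
    sequence: str
    family: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        if not set(self.sequence) <= set("ACGU"):
            raise ValueError(f"mature {self.name!r}: non-RNA characters")
        if not self.family:
            m = _FAMILY_RE.search(self.name)
            self.family = m.group(1) if m else self.name


def load_mature_library(records: Iterable[ReadRecord]) -> list[MatureMiRNA]:
    return [MatureMiRNA(name=r.id, sequence=r.sequence) for r in records]


# ---------------------------------------------------------------------------
# homology scan

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp_dna(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class SeedHit:
    source_id: str
    position: int  # 1-based start of the mature homolog on the plus strand
    mature: MatureMiRNA
    strand: str  # '+' or '-'
    mismatches: int


def homology_scan(
    sequences: Sequence[ReadRecord],
    mature_library: Sequence[MatureMiRNA],
    max_mismatches: int = 2,
) -> list[SeedHit]:
    """Report every ungapped occurrence of each mature miRNA (and its
    reverse complement) with at most ``max_mismatches`` substitutions.
    DNA/RNA alphabets are reconciled (T == U)."""
    for mature in mature_library:
        if len(mature.sequence) < 16:
            raise ValueError(f"mature {mature.name!r} shorter than 16 nt")
    hits: list[SeedHit] = []
    for rec in sequences:
        seq = rec.sequence.upper().replace("U", "T")
        enc = np.frombuffer(seq.encode(), dtype=np.uint8)
        for mature in mature_library:
            probe_fwd = mature.sequence.replace("U", "T")
            m = len(probe_fwd)
            if len(seq) < m:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(enc, m)
            for probe, strand in ((probe_fwd, "+"), (_revcomp_dna(probe_fwd), "-")):
                penc = np.frombuffer(probe.encode(), dtype=np.uint8)
                mm_counts = (windows != penc).sum(axis=1)
                for start in np.flatnonzero(mm_counts <= max_mismatches):
                    hits.append(
                        SeedHit(
                            rec.id, int(start) + 1, mature, strand, int(mm_counts[start])
                        )
                    )
    hits.sort(key=lambda h: (h.source_id, h.position, h.mature.name, h.strand))
    return hits


# ---------------------------------------------------------------------------
# folding engine (pluggable: sequence -> (dot-bracket, mfe))

PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}
STACK_BONUS = -0.5
#: charged when a pair closes a region whose optimum is not the adjacent
#: stacked pair — the analogue of loop-initiation penalties in full
#: nearest-neighbour models (Turner hairpin/multibranch initiation is
#: +5 to +9 kcal/mol); keeps isolated pairs and scattered short helices
#: unprofitable so random RNA folds near the energy scale RNAfold reports
LOOP_PENALTY = 8.0
MIN_LOOP = 3

FoldingEngine = Callable[[str], tuple[str, float]]


def fold(sequence: str) -> tuple[str, float]:
    """Fold an RNA with the bundled simplified pair-energy model.

    Returns (dot-bracket structure, MFE in kcal/mol, always <= 0).
    Dynamic program over subsequence energies: W(i,j) is the optimum for
    i..j; V(i,j) the optimum with (i,j) paired, where pairing costs the
    pair energy plus either a stacking bonus (inner pair adjacent) or a
    loop-opening penalty.
    """
    rna = sequence.upper().replace("T", "U")
    n = len(rna)
    if n == 0:
        return "", 0.0
    enc = np.frombuffer(rna.encode(), dtype=np.uint8)
    pair_e = np.full((n, n), np.inf)
    for (a, b), e in PAIR_ENERGY.items():
        mask = (enc[:, None] == ord(a)) & (enc[None, :] == ord(b))
        pair_e[mask] = e
    # forbid tight loops
    ii, jj = np.indices((n, n))
    pair_e[jj - ii <= MIN_LOOP] = np.inf

    W = np.zeros((n, n))
    V = np.full((n, n), np.inf)
    for d in range(MIN_LOOP + 1, n):
        i = np.arange(0, n - d)
        j = i + d
        inner = np.minimum(V[i + 1, j - 1] + STACK_BONUS, W[i + 1, j - 1] + LOOP_PENALTY)
        V[i, j] = pair_e[i, j] + inner
        for a in i:
            b = a + d
            ks = np.arange(a, b)
            bif = (W[a, ks] + W[ks + 1, b]).min()
            W[a, b] = min(V[a, b], bif)

    structure = ["."] * n
    stack: list[tuple[int, int, str]] = [(0, n - 1, "W")]
    eps = 1e-9
    while stack:
        a, b, state = stack.pop()
        if b - a <= MIN_LOOP:
            continue
        if state == "W":
            if W[a, b] >= -eps:
                continue
            if abs(W[a, b] - V[a, b]) < eps:
                stack.append((a, b, "V"))
                continue
            for k in range(a, b):
                if abs(W[a, k] + W[k + 1, b] - W[a, b]) < eps:
                    stack.append((a, k, "W"))
                    stack.append((k + 1, b, "W"))
                    break
        else:
            structure[a], structure[b] = "(", ")"
            inner_stack = V[a + 1, b - 1] + STACK_BONUS
            if abs(V[a, b] - (pair_e[a, b] + inner_stack)) < eps:
                stack.append((a + 1, b - 1, "V"))
            else:
                stack.append((a + 1, b - 1, "W"))
    mfe = float(min(W[0, n - 1], 0.0))
    return "".join(structure), mfe


def pair_table(structure: str) -> list[int]:
    """0-based partner index per position, -1 for unpaired. Raises on
    unbalanced dot-bracket."""
    partners = [-1] * len(structure)
    stack = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            partners[i], partners[j] = j, i
    if stack:
        raise ValueError("unbalanced structure")
    return partners


def mfei(mfe: float, length: int, gc_content: float) -> float:
    """MFEI = (−MFE per 100 nt) / GC percentage."""
    if length <= 0 or gc_content <= 0:
        raise ValueError("length and gc_content must be positive")
    return (-mfe / length * 100.0) / (gc_content * 100.0)


def gc_fraction(sequence: str) -> float:
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(s) if s else 0.0


# ---------------------------------------------------------------------------
# candidate extraction


@dataclass
class HairpinCandidate:
    source_id: str
    locus_start: int  # 1-based on the source sequence (plus strand)
    locus_end: int
    mature: MatureMiRNA | None
    precursor_seq: str
    structure: str
    mfe: float
    gc_content: float
    mfei: float
    mature_arm: str  # '5p', '3p' or '?'
    mature_mismatches_to_query: int = 0
    duplex_unpaired: int = 0
    verdict: str = "pending"
    mature_offset: int = 0  # 0-based mature start within precursor_seq
    rejection_reason: str | None = field(default=None)

    @property
    def length(self) -> int:
        return len(self.precursor_seq)

    @property
    def accepted(self) -> bool:
        return self.verdict == "accepted"


def extract_and_fold(
    hit: SeedHit,
    sequences_by_id: Mapping[str, str],
    flank: int = 200,
    folding_engine: FoldingEngine = fold,
) -> HairpinCandidate:
    """Extract the candidate window around a mature hit, fold it, trim it
    to the hairpin enclosing the mature, and compute MFE/GC/MFEI.

    The window is ``flank`` nt each side of the mature homolog, truncated
    at sequence ends; minus-strand hits are reverse-complemented so the
    mature reads in sense orientation. The precursor is the folded
    region delimited by the mature and its pairing partners, extended
    outward through closing base pairs; MFE and MFEI are recomputed on the
    trimmed precursor.
    """
    source = sequences_by_id[hit.source_id].upper().replace("U", "T")
    m = len(hit.mature.sequence)
    w_start = max(1, hit.position - flank)
    w_end = min(len(source), hit.position + m - 1 + flank)
    window = source[w_start - 1 : w_end]
    if hit.strand == "-":
        window = _revcomp_dna(window)
        mat_off = w_end - (hit.position + m - 1)
    else:
        mat_off = hit.position - w_start

    if len(window) < m + 20:
        return _rejected_candidate(hit, w_start, w_end, window, "too_short")

    structure, _ = folding_engine(window.replace("T", "U"))
    partners = pair_table(structure)
    mat_positions = range(mat_off, mat_off + m)
    mat_partners = [partners[p] for p in mat_positions if partners[p] >= 0]
    if not mat_partners:
        return _rejected_candidate(hit, w_start, w_end, window, "no_hairpin")

    lo = min(min(mat_positions), min(mat_partners))
    hi = max(max(mat_positions), max(mat_partners))
    # extend outward along closing pairs of the enclosing stem
    while lo - 1 >= 0 and partners[lo - 1] == hi + 1:
        lo -= 1
        hi += 1
    precursor = window[lo : hi + 1]
    pre_struct, pre_mfe = folding_engine(precursor.replace("T", "U"))
    pre_partners = pair_table(pre_struct)
    pre_mat_off = mat_off - lo
    mat_struct = pre_struct[pre_mat_off : pre_mat_off + m]
    if "(" in mat_struct and ")" in mat_struct:
        arm = "?"
    elif ")" in mat_struct:
        arm = "3p"
    elif "(" in mat_struct:
        arm = "5p"
    else:
        arm = "?"
    gc = gc_fraction(precursor)
    cand = HairpinCandidate(
        source_id=hit.source_id,
        locus_start=w_start + (lo if hit.strand == "+" else len(window) - 1 - hi),
        locus_end=w_start + (hi if hit.strand == "+" else len(window) - 1 - lo),
        mature=hit.mature,
        precursor_seq=precursor.replace("T", "U"),
        structure=pre_struct,
        mfe=pre_mfe,
        gc_content=gc,
        mfei=mfei(pre_mfe, len(precursor), gc) if gc > 0 and pre_mfe < 0 else 0.0,
        mature_arm=arm,
        mature_mismatches_to_query=hit.mismatches,
        duplex_unpaired=sum(
            1 for p in range(pre_mat_off, pre_mat_off + m) if pre_partners[p] < 0
        ),
        mature_offset=pre_mat_off,
    )
    return cand


def _rejected_candidate(hit, w_start, w_end, window, reason) -> HairpinCandidate:
    return HairpinCandidate(
        source_id=hit.source_id,
        locus_start=w_start,
        locus_end=w_end,
        mature=hit.mature,
        precursor_seq=window.replace("T", "U"),
        structure="." * len(window),
        mfe=0.0,
        gc_content=gc_fraction(window),
        mfei=0.0,
        mature_arm="?",
        mature_mismatches_to_query=hit.mismatches,
        duplex_unpaired=len(hit.mature.sequence),
        verdict=f"rejected({reason})",
        rejection_reason=reason,
    )


# ---------------------------------------------------------------------------
# acceptance criteria


@dataclass
class HairpinCriteria:
    """Defaults: mature in one arm (not spanning the terminal loop), <= 4
    unpaired mature positions, MFEI >= 0.67 (above the tRNA/rRNA/mRNA
    range), precursor 60-300 nt. All comparisons inclusive."""

    max_duplex_unpaired: int = 4
    min_mfei: float = 0.67
    min_length: int = 60
    max_length: int = 300


def apply_criteria(
    candidate: HairpinCandidate, criteria: HairpinCriteria | None = None
) -> HairpinCandidate:
    """Assign the accept/reject verdict; the first failing criterion is
    recorded as the rejection reason."""
    criteria = criteria or HairpinCriteria()
    if candidate.rejection_reason is not None:
        return candidate

    def reject(reason: str) -> HairpinCandidate:
        candidate.verdict = f"rejected({reason})"
        candidate.rejection_reason = reason
        return candidate

    if candidate.mature_arm == "?":
        return reject("loop_spanning")
    if candidate.duplex_unpaired > criteria.max_duplex_unpaired:
        return reject("duplex_unpaired")
    if candidate.mfei < criteria.min_mfei:
        return reject("mfei")
    if not (criteria.min_length <= candidate.length <= criteria.max_length):
        return reject("length")
    candidate.verdict = "accepted"
    return candidate


def collapse_overlapping(candidates: Sequence[HairpinCandidate]) -> list[HairpinCandidate]:
    """Collapse overlapping accepted candidates for the same mature to the
    best-MFEI locus."""
    accepted = [c for c in candidates if c.accepted]
    rest = [c for c in candidates if not c.accepted]
    kept: list[HairpinCandidate] = []
    for cand in sorted(accepted, key=lambda c: -c.mfei):
        overlap = any(
            k.source_id == cand.source_id
            and k.mature is cand.mature
            and not (cand.locus_end < k.locus_start or cand.locus_start > k.locus_end)
            for k in kept
        )
        if not overlap:
            kept.append(cand)
    return kept + rest


# ---------------------------------------------------------------------------
# family summaries


def summarize_families(
    accepted: Sequence[HairpinCandidate],
) -> tuple[dict[str, int], int, dict[str, float]]:
    """Per-family locus counts, unique mature miRNA count, and family
    fractions (fractions sum to 1 over a non-empty set)."""
    counts: dict[str, int] = {}
    matures: set[str] = set()
    for c in accepted:
        fam = c.mature.family if c.mature else "?"
        counts[fam] = counts.get(fam, 0) + 1
        if c.mature:
            matures.add(c.mature.name)
    total = sum(counts.values())
    fractions = {f: n / total for f, n in counts.items()} if total else {}
    return counts, len(matures), fractions


def compare_repertoires(
    sets_by_chromosome: Mapping[str, Iterable[str]],
) -> dict[str, dict[str, bool]]:
    """Presence/absence matrix of miRNA families per chromosome set."""
    all_families = sorted({f for fams in sets_by_chromosome.values() for f in fams})
    return {
        fam: {chrom: fam in set(fams) for chrom, fams in sets_by_chromosome.items()}
        for fam in all_families
    }


def repertoire_differences(
    matrix: Mapping[str, Mapping[str, bool]]
) -> dict[str, list[str]]:
    """Families private to each set (absent from every other set)."""
    chroms = sorted({c for row in matrix.values() for c in row})
    return {
        chrom: [
            fam
            for fam, row in matrix.items()
            if row.get(chrom) and not any(row.get(c) for c in chroms if c != chrom)
        ]
        for chrom in chroms
    }
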
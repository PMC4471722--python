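"""Read triage and repeat-composition summaries.

Survey reads are classified into exactly one of five categories —
repeat, chloroplast, mitochondrion, rRNA, low_copy — using repeat
annotations and homology matches against organellar/rRNA references.
Low-copy reads are the input set for downstream low-copy-number (LCN)
assembly. Repeat composition is summarised per superfamily and family on
the union of masked intervals, so overlapping annotations are never
double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import HomologyMatch, ReadRecord, RepeatAnnotation

#: fixed category precedence; a read matching several lines of evidence is
#: assigned the highest-precedence category so counts partition the set.
CATEGORY_PRECEDENCE = ("repeat", "chloroplast", "mitochondrion", "rRNA", "low_copy")


@dataclass
class TriageThresholds:
    """E-value cutoffs for organellar/rRNA exclusion (inclusive)."""

    chloroplast_evalue: float = 1e-15
    mitochondrion_evalue: float = 1e-15
    rrna_evalue: float = 1e-5


@dataclass
class TriageDecision:
    read_id: str
    category: str
    evidence: HomologyMatch | RepeatAnnotation | None = None


@dataclass
class RepeatComposition:
    """Masked-base composition of a read set.

    Fractions are percentages of total read bases; the per-read percentage
    (fraction of reads carrying any repeat) is emitted alongside because
    survey reports are sometimes phrased per read rather than per base.
    """

    total_bases: int
    superfamily_fraction_pct: dict[str, float] = field(default_factory=dict)
    family_masked_bases: dict[str, int] = field(default_factory=dict)
    total_repetitive_fraction_pct: float = 0.0
    repetitive_read_fraction_pct: float | None = None

    def to_frame(self) -> pd.DataFrame:
        fam_by_sf: dict[str, list[str]] = {}
        for fam in self.family_masked_bases:
            fam_by_sf.setdefault(fam[:3], []).append(fam)
        rows = []
        for sf, frac in sorted(
            self.superfamily_fraction_pct.items(), key=lambda kv: -kv[1]
        ):
            fams = sorted(
                fam_by_sf.get(sf, []), key=lambda f: -self.family_masked_bases[f]
            )
            rows.append(
                {
                    "superfamily": sf,
                    "families": ",".join(fams),
                    "masked_bases": sum(self.family_masked_bases[f] for f in fams),
                    "fraction_pct": frac,
                }
            )
        return pd.DataFrame(rows)


def _interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total covered length of 1-based inclusive intervals."""
    merged = 0
    current: tuple[int, int] | None = None
    for start, end in sorted(intervals):
        if current is None or start > current[1] + 1:
            if current is not None:
                merged += current[1] - current[0] + 1
            current = (start, end)
        else:
            current = (current[0], max(current[1], end))
    if current is not None:
        merged += current[1] - current[0] + 1
    return merged


def triage_reads(
    reads: Sequence[ReadRecord],
    repeat_annotations: Sequence[RepeatAnnotation] = (),
    chloroplast_matches: Sequence[HomologyMatch] = (),
    mitochondrion_matches: Sequence[HomologyMatch] = (),
    rrna_matches: Sequence[HomologyMatch] = (),
    thresholds: TriageThresholds | None = None,
) -> list[TriageDecision]:
    """Assign each read exactly one category by fixed precedence
    repeat > chloroplast > mitochondrion > rRNA > low_copy.

    A repeat annotation of any length triggers the repeat category;
    organellar and rRNA matches must pass their (inclusive) e-value
    cutoffs. Evidence referencing an unknown read id is an error.
    """
    thresholds = thresholds or TriageThresholds()
    known = {r.id for r in reads}

    def best_by_read(
        matches: Sequence[HomologyMatch], cutoff: float
    ) -> dict[str, HomologyMatch]:
        best: dict[str, HomologyMatch] = {}
        for m in matches:
            if m.query_id not in known:
                raise ValueError(f"evidence references unknown read {m.query_id!r}")
            if m.evalue > cutoff:
                continue
            cur = best.get(m.query_id)
            if cur is None or (m.evalue, -m.bitscore) < (cur.evalue, -cur.bitscore):
                best[m.query_id] = m
        return best

    repeat_by_read: dict[str, RepeatAnnotation] = {}
    for ann in repeat_annotations:
        if ann.target_id not in known:
            raise ValueError(f"repeat annotation references unknown read {ann.target_id!r}")
        cur = repeat_by_read.get(ann.target_id)
        if cur is None or len(ann) > len(cur):
            repeat_by_read[ann.target_id] = ann

    chloro = best_by_read(chloroplast_matches, thresholds.chloroplast_evalue)
    mito = best_by_read(mitochondrion_matches, thresholds.mitochondrion_evalue)
    rrna = best_by_read(rrna_matches, thresholds.rrna_evalue)

    decisions = []
    for read in reads:
        if read.id in repeat_by_read:
            decisions.append(TriageDecision(read.id, "repeat", repeat_by_read[read.id]))
        elif read.id in chloro:
            decisions.append(TriageDecision(read.id, "chloroplast", chloro[read.id]))
        elif read.id in mito:
            decisions.append(TriageDecision(read.id, "mitochondrion", mito[read.id]))
        elif read.id in rrna:
            decisions.append(TriageDecision(read.id, "rRNA", rrna[read.id]))
        else:
            decisions.append(TriageDecision(read.id, "low_copy", None))
    return decisions


def low_copy_reads(
    reads: Sequence[ReadRecord], decisions: Sequence[TriageDecision]
) -> list[ReadRecord]:
    """The assembly input set: reads triaged as low_copy."""
    keep = {d.read_id for d in decisions if d.category == "low_copy"}
    return [r for r in reads if r.id in keep]


def summarize_repeats(
    repeat_annotations: Sequence[RepeatAnnotation],
    total_bases: int,
    read_lengths: Mapping[str, int] | None = None,
    n_reads: int | None = None,
) -> RepeatComposition:
    """Base-level repeat composition on the union of masked intervals.

    ``read_lengths`` (id -> length), when given, bounds-checks annotations
    and enables the per-read repetitive percentage when ``n_reads`` is set.
    """
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    by_read: dict[str, list[RepeatAnnotation]] = {}
    for ann in repeat_annotations:
        if read_lengths is not None:
            length = read_lengths.get(ann.target_id)
            if length is None:
                raise ValueError(f"annotation on unknown read {ann.target_id!r}")
            if ann.end > length:
                raise ValueError(
                    f"annotation {ann.start}-{ann.end} outside read "
                    f"{ann.target_id!r} (length {length})"
                )
        by_read.setdefault(ann.target_id, []).append(ann)

    sf_bases: dict[str, int] = {}
    fam_bases: dict[str, int] = {}
    total_masked = 0
    for anns in by_read.values():
        total_masked += _interval_union_length((a.start, a.end) for a in anns)
        # per-superfamily/family unions computed separately so that a base
        # annotated by two families counts once in the total but is credited
        # to each family's own cumulative track
        for key, group in _group(anns, lambda a: a.superfamily_code).items():
            sf_bases[key] = sf_bases.get(key, 0) + _interval_union_length(
                (a.start, a.end) for a in group
            )
        for key, group in _group(anns, lambda a: a.family).items():
            fam_bases[key] = fam_bases.get(key, 0) + _interval_union_length(
                (a.start, a.end) for a in group
            )

    comp = RepeatComposition(
        total_bases=total_bases,
        superfamily_fraction_pct={
            sf: round(100.0 * b / total_bases, 2) for sf, b in sf_bases.items()
        },
        family_masked_bases=fam_bases,
        total_repetitive_fraction_pct=round(100.0 * total_masked / total_bases, 2),
    )
    if n_reads:
        comp.repetitive_read_fraction_pct = round(100.0 * len(by_read) / n_reads, 2)
    return comp


def _group(items, key):
    out: dict[str, list] = {}
    for it in items:
        out.setdefault(key(it), []).append(it)
    return out


def lightweight_mask(
    reads: Sequence[ReadRecord],
    repeat_library: Sequence[ReadRecord],
    k: int = 15,
    min_hit_len: int = 50,
) -> list[RepeatAnnotation]:
    """Exact k-mer seeded, ungapped-extended repeat masking against a
    library whose headers carry coded family names (e.g. RLG-...).

    A deliberately small stand-in for a full repeat masker: real analyses
    ingest RepeatMasker ``.out`` files via seqio; this matcher exists so
    synthetic data can be masked end-to-end.
    """
    if not repeat_library:
        raise ValueError("repeat library is empty")
    index: dict[str, list[tuple[int, int]]] = {}
    for li, lib in enumerate(repeat_library):
        s = lib.sequence
        for i in range(len(s) - k + 1):
            index.setdefault(s[i : i + k], []).append((li, i))

    annotations: list[RepeatAnnotation] = []
    for read in reads:
        covered: list[tuple[int, int, int]] = []  # (start0, end0, lib index)
        s = read.sequence
        i = 0
        while i <= len(s) - k:
            hits = index.get(s[i : i + k])
            if hits:
                li, lpos = hits[0]
                lib = repeat_library[li].sequence
                # ungapped extension with mismatches allowed while local
                # identity stays high; stop after 3 consecutive mismatches
                rs, ls_ = i, lpos
                while rs > 0 and ls_ > 0 and s[rs - 1] == lib[ls_ - 1]:
                    rs -= 1
                    ls_ -= 1
                re_, le_ = i + k - 1, lpos + k - 1
                streak = 0
                while re_ + 1 < len(s) and le_ + 1 < len(lib):
                    if s[re_ + 1] == lib[le_ + 1]:
                        streak = 0
                    else:
                        streak += 1
                        if streak > 3:
                            break
                    re_ += 1
                    le_ += 1
                re_ -= streak
                if re_ - rs + 1 >= min_hit_len:
                    covered.append((rs, re_, li))
                    i = re_ + 1
                    continue
            i += 1
        for rs, re_, li in covered:
            fam = repeat_library[li].id
            annotations.append(
                RepeatAnnotation(
                    target_id=read.id,
                    start=rs + 1,
                    end=re_ + 1,
                    family=fam,
                    superfamily_code=fam[:3],
                )
            )
    return annotations
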
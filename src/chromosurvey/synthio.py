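"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the data-generating process of a flow-sorted,
MDA-amplified, 454-sequenced repeat-rich chromosome: a chromosome
sequence dominated by transposable-element copies (default 85%
repetitive) with planted gene fragments and miRNA precursor hairpins;
read sets with configurable sorting purity (off-target organellar/rRNA
contaminant reads) and optional MDA-like per-locus copy bias; homology
match tables with planted reciprocal-best-hit orthologs and optional
RBH-violating decoys; and transcript quartets for two genotypes x two
conditions carrying planted variants of the three cross-genotype
archetypes.

Everything is seed-deterministic, and the returned SyntheticTruth is
sufficient to score every downstream stage's recall and precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .seqio import HomologyMatch, ReadRecord, read_fasta

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class CapacityError(ValueError):
    """Requested features exceed the available chromosome space."""


def _data_path(name: str):
    return str(resources.files("chromosurvey") / "_data" / name)


def load_repeat_library() -> list[ReadRecord]:
    return read_fasta(_data_path("synthetic_repeat_library.fa"))


def load_contaminant_decoys() -> list[ReadRecord]:
    return read_fasta(_data_path("synthetic_organellar_decoys.fa"))


def load_bundled_matures() -> list[ReadRecord]:
    return read_fasta(_data_path("synthetic_mature_mirnas.fa"))


@dataclass
class GenerationConfig:
    """Study-condition defaults for the synthetic chromosome."""

    length: int = 200_000
    repeat_fraction: float = 0.85
    n_genes: int = 12
    n_mirna_loci: int = 6
    seed: int = 0
    gc: float = 0.46
    repeat_divergence: float = 0.0
    gene_len_range: tuple[int, int] = (900, 2400)
    bias_sigma: float = 0.5
    bias_locus_size: int = 10_000

    def __post_init__(self) -> None:
        if self.length < 10_000:
            raise ValueError("length must be >= 10,000")
        if not (0 <= self.repeat_fraction < 1):
            raise ValueError("repeat_fraction must be in [0, 1)")


@dataclass
class SyntheticTruth:
    chromosome_length: int
    repeat_intervals: list[tuple[int, int, str, str]] = field(default_factory=list)
    gene_loci: list[tuple[int, int, str, str]] = field(default_factory=list)
    mirna_loci: list[tuple[int, int, str, str]] = field(default_factory=list)
    contaminant_read_ids: set[str] = field(default_factory=set)
    #: on-target read placements, read_id -> (start, end) 1-based on the chromosome
    read_origins: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_variants: list["PlantedVariant"] = field(default_factory=list)
    copy_bias_factors: np.ndarray | None = None
    bias_locus_size: int = 10_000

    def repeat_fraction(self) -> float:
        return sum(e - s + 1 for s, e, _, _ in self.repeat_intervals) / self.chromosome_length

    def validate(self) -> None:
        for coll in (self.repeat_intervals, self.gene_loci, self.mirna_loci):
            for start, end, *_ in coll:
                if not (1 <= start <= end <= self.chromosome_length):
                    raise ValueError(f"interval {start}-{end} outside chromosome")


@dataclass
class PlantedVariant:
    transcript_id: str
    position: int  # 1-based on the transcript
    genotype: str  # 'TR' or 'TTD'
    base: str
    group: int  # archetype 1, 2 or 3
    b5_base: str = ""


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    if divergence <= 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < divergence
    for i in np.flatnonzero(hits):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_precursor(mature_rna: str, rng: np.random.Generator, stem_ext: int = 20,
                    loop_len: int = 18) -> tuple[str, int]:
    """A planted precursor hairpin: [ext | mature | loop | revcomp(mature+ext)].

    Returns (DNA sequence, 0-based mature offset). The mature sits in the
    5' arm, fully paired against its star strand.
    """
    mature_dna = mature_rna.replace("U", "T")
    ext = _random_seq(rng, stem_ext, 0.5)
    loop = _random_seq(rng, loop_len, 0.4)
    arm5 = ext + mature_dna
    return arm5 + loop + _revcomp(arm5), stem_ext


#: weights favouring Gypsy-heavy grass-like composition, keyed by family prefix
_SUPERFAMILY_WEIGHTS = {"RLG": 0.55, "RLC": 0.15, "DTC": 0.17, "DTA": 0.03,
                        "RIX": 0.05, "RLX": 0.03, "DTM": 0.02}


def generate_chromosome(config: GenerationConfig) -> tuple[str, SyntheticTruth]:
    """Generate a chromosome sequence and its planted truth.

    Features (repeat copies, gene loci, miRNA precursors) are laid out
    non-overlapping in shuffled order with the non-repetitive remainder
    distributed randomly between them, so the realised repeat fraction
    equals the configured one up to the final copy's truncation.
    """
    rng = np.random.default_rng(config.seed)
    library = load_repeat_library()
    matures = load_bundled_matures()

    features: list[tuple[str, str, str]] = []  # (kind, label, sequence)

    gene_specs = []
    for i in range(config.n_genes):
        glen = int(rng.integers(config.gene_len_range[0], config.gene_len_range[1] + 1))
        seq = _random_seq(rng, glen, 0.5)
        gene_specs.append((f"gene{i:04d}", seq))
        features.append(("gene", f"gene{i:04d}", seq))

    mirna_offsets: dict[str, tuple[str, int]] = {}
    for i in range(config.n_mirna_loci):
        mat = matures[i % len(matures)]
        precursor, offset = build_precursor(mat.sequence.replace("T", "U"), rng)
        label = f"mirna{i:04d}:{mat.id}"
        features.append(("mirna", label, precursor))
        mirna_offsets[label] = (mat.id, offset)

    nonrepeat_feature_bases = sum(len(s) for _, _, s in features)
    repeat_target = int(round(config.repeat_fraction * config.length))
    free = config.length - nonrepeat_feature_bases - repeat_target
    if free < 0:
        raise CapacityError(
            f"features need {nonrepeat_feature_bases + repeat_target} bases but the "
            f"chromosome has only {config.length}"
        )

    weights = np.array([_SUPERFAMILY_WEIGHTS.get(r.id[:3], 0.01) for r in library])
    weights = weights / weights.sum()
    placed_repeat = 0
    while placed_repeat < repeat_target:
        lib = library[rng.choice(len(library), p=weights)]
        copy = lib.sequence
        if len(copy) > 200 and rng.random() < 0.3:  # truncated/fragmented copies
            cut = int(rng.integers(150, len(copy)))
            copy = copy[:cut]
        if placed_repeat + len(copy) > repeat_target:
            copy = copy[: repeat_target - placed_repeat]
        if len(copy) < 50:
            placed_repeat += len(copy)  # too short to annotate; absorb as filler
            features.append(("filler", "", _random_seq(rng, len(copy), config.gc)))
            continue
        copy = _mutate(rng, copy, config.repeat_divergence)
        features.append(("repeat", lib.id, copy))
        placed_repeat += len(copy)

    order = rng.permutation(len(features))
    gap_split = rng.multinomial(free, np.ones(len(features) + 1) / (len(features) + 1))

    truth = SyntheticTruth(chromosome_length=config.length,
                           bias_locus_size=config.bias_locus_size)
    parts: list[str] = []
    cursor = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        start = cursor + 1
        parts.append(seq)
        cursor += len(seq)
        return start, cursor

    emit(_random_seq(rng, int(gap_split[0]), config.gc))
    for slot, idx in enumerate(order):
        kind, label, seq = features[idx]
        start, end = emit(seq)
        if kind == "repeat":
            truth.repeat_intervals.append((start, end, label, label[:3]))
        elif kind == "gene":
            truth.gene_loci.append((start, end, f"ref_{label}", "brachypodium"))
        elif kind == "mirna":
            mat_id, offset = mirna_offsets[label]
            truth.mirna_loci.append((start, end, mat_id, "5p"))
        emit(_random_seq(rng, int(gap_split[slot + 1]), config.gc))

    n_loci = max(1, config.length // config.bias_locus_size)
    truth.copy_bias_factors = np.exp(rng.normal(0.0, config.bias_sigma, size=n_loci))
    truth.gene_loci.sort()
    truth.mirna_loci.sort()
    truth.repeat_intervals.sort()
    truth.validate()
    sequence = "".join(parts)
    assert len(sequence) == config.length
    return sequence, truth


def simulate_reads(
    chromosome: str,
    truth: SyntheticTruth,
    n_reads: int,
    mean_len: float = 357.0,
    len_sd: float = 120.0,
    purity: float = 0.9524,
    bias_on: bool = False,
    seed: int = 0,
    library: str = "synthlib-1",
) -> list[ReadRecord]:
    """Simulate single-end survey reads.

    Each read is on-target with probability ``purity``; off-target reads
    are drawn from the bundled organellar/rRNA decoys and their ids are
    recorded in ``truth.contaminant_read_ids``. With ``bias_on``,
    on-target start positions are drawn per-locus according to
    ``truth.copy_bias_factors`` (MDA-like log-normal copy bias);
    otherwise uniformly. Read lengths are normal, truncated to [50, 1200].
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    decoys = load_contaminant_decoys()
    L = len(chromosome)
    locus = truth.bias_locus_size
    n_loci = max(1, L // locus)
    if bias_on:
        w = np.asarray(truth.copy_bias_factors, dtype=float)[:n_loci]
        locus_p = w / w.sum()
    reads: list[ReadRecord] = []
    lengths = np.clip(rng.normal(mean_len, len_sd, size=n_reads), 50, 1200).astype(int)
    on_target = rng.random(n_reads) < purity
    for i in range(n_reads):
        rid = f"read{i:07d}"
        rlen = int(lengths[i])
        if on_target[i]:
            if bias_on:
                li = rng.choice(n_loci, p=locus_p)
                lo = li * locus
                hi = min(L, lo + locus)
                start = int(rng.integers(lo, hi))
            else:
                start = int(rng.integers(0, max(1, L - rlen + 1)))
            seq = chromosome[start : start + rlen]
            if len(seq) < 50:
                start = max(0, L - rlen)
                seq = chromosome[start:L]
            truth.read_origins[rid] = (start + 1, start + len(seq))
        else:
            d = decoys[rng.integers(len(decoys))]
            dmax = max(1, len(d.sequence) - rlen + 1)
            start = int(rng.integers(0, dmax))
            seq = d.sequence[start : start + min(rlen, len(d.sequence))]
            truth.contaminant_read_ids.add(rid)
        reads.append(ReadRecord(id=rid, sequence=seq, library=library))
    return reads


def truth_repeat_annotations(
    truth: SyntheticTruth, reads: Sequence[ReadRecord]
) -> list["RepeatAnnotation"]:
    """Project the planted repeat intervals onto on-target reads — the
    annotation set a perfect repeat masker would produce, used to score
    masker recall and fraction recovery against ground truth."""
    from .seqio import RepeatAnnotation

    import bisect

    intervals = truth.repeat_intervals
    starts = [s for s, _e, _f, _c in intervals]
    max_len = max((e - s + 1 for s, e, _f, _c in intervals), default=0)
    annotations = []
    for read in reads:
        origin = truth.read_origins.get(read.id)
        if origin is None:
            continue
        r_start, r_end = origin
        idx = bisect.bisect_right(starts, r_end)
        lo_idx = bisect.bisect_left(starts, r_start - max_len)
        for s, e, fam, code in intervals[lo_idx:idx]:
            lo, hi = max(s, r_start), min(e, r_end)
            if lo <= hi:
                annotations.append(
                    RepeatAnnotation(
                        target_id=read.id,
                        start=lo - r_start + 1,
                        end=hi - r_start + 1,
                        family=fam,
                        superfamily_code=code,
                    )
                )
    return annotations


# ---------------------------------------------------------------------------
# homology match tables


def emit_match_tables(
    truth: SyntheticTruth,
    proteome_specs: Mapping[str, Mapping[str, tuple[str, str, int]]],
    seed: int = 0,
    decoys: Sequence[tuple[str, str, str]] = (),
) -> dict[str, dict[str, list[HomologyMatch]]]:
    """Emit forward/reverse 12-column match tables per reference set.

    ``proteome_specs`` maps species -> {gene_id: (protein_id, model
    chromosome, model position)}; every planted ortholog yields a mutual
    best hit. ``decoys`` rows (species, gene_id, protein_id) produce
    asymmetric pairs that violate the reciprocal-best-hit property: the
    forward search ranks the decoy protein best for the gene, but the
    protein's own best reverse hit is a different query.
    """
    rng = np.random.default_rng(seed)
    lengths_by_gene = {
        ref[4:]: end - start + 1 for start, end, ref, _ in truth.gene_loci
    }
    tables: dict[str, dict[str, list[HomologyMatch]]] = {}
    for species, orthologs in proteome_specs.items():
        fwd: list[HomologyMatch] = []
        rev: list[HomologyMatch] = []
        for gene_id, (protein_id, _chrom, _pos) in sorted(orthologs.items()):
            glen = lengths_by_gene.get(gene_id, 1200)
            alen = max(30, glen // 3)
            ppos = float(92 + 6 * rng.random())
            pident = float(95 + 4 * rng.random())
            bits = float(200 + 400 * rng.random())
            kw = dict(pident=round(pident, 2), align_len=alen, qstart=1, qend=glen,
                      sstart=1, send=alen, evalue=1e-80, bitscore=round(bits, 1),
                      ppos=round(ppos, 2))
            fwd.append(HomologyMatch(query_id=gene_id, subject_id=protein_id,
                                     search_direction="query-vs-protein", **kw))
            rev.append(HomologyMatch(query_id=protein_id, subject_id=gene_id,
                                     search_direction="protein-vs-query", **kw))
        for d_species, d_gene, d_protein in decoys:
            if d_species != species:
                continue
            other_gene = next(
                (g for g in sorted(orthologs) if g != d_gene), f"{d_gene}_alt"
            )
            kw = dict(pident=96.0, align_len=300, qstart=1, qend=900, sstart=1,
                      send=300, ppos=95.0)
            # forward: decoy protein is the gene's best hit
            fwd.append(HomologyMatch(query_id=d_gene, subject_id=d_protein,
                                     evalue=1e-90, bitscore=700.0,
                                     search_direction="query-vs-protein", **kw))
            # reverse: the protein's best hit is a different gene
            rev.append(HomologyMatch(query_id=d_protein, subject_id=other_gene,
                                     evalue=1e-95, bitscore=750.0,
                                     search_direction="protein-vs-query", **kw))
            rev.append(HomologyMatch(query_id=d_protein, subject_id=d_gene,
                                     evalue=1e-60, bitscore=300.0,
                                     search_direction="protein-vs-query", **kw))
        tables[species] = {"forward": fwd, "reverse": rev}
    return tables


# ---------------------------------------------------------------------------
# transcript quartets with planted variants


_TRIO_SETS = ("TR-drought", "TR-control", "TTD-drought", "TTD-control")


def generate_transcript_trio(
    truth: SyntheticTruth,
    chromosome: str,
    n_transcripts: int | None = None,
    variant_density: float = 1.0 / 1000,
    group_proportions: tuple[float, float, float] = (0.45, 0.45, 0.10),
    seed: int = 0,
    edge_margin: int = 150,
    min_spacing: int = 12,
) -> tuple[dict[str, list[ReadRecord]], list[PlantedVariant]]:
    """Transcript sets for two genotypes x two conditions with planted
    variants.

    Transcripts are the planted gene sequences (the chromosome supplies
    the B5 base at every position). Variants are planted at
    ``variant_density`` per base in archetype proportions (Group 1: TR
    differs, TTD matches B5; Group 2: TR == TTD differ from B5; Group 3:
    all three distinct), spaced ``min_spacing`` apart and away from
    transcript ends. Within each genotype the drought and control sets
    carry identical bases at every planted position, so the consistency
    requirement is satisfiable by construction.
    """
    rng = np.random.default_rng(seed)
    loci = truth.gene_loci[: n_transcripts or len(truth.gene_loci)]
    sets: dict[str, list[ReadRecord]] = {name: [] for name in _TRIO_SETS}
    planted: list[PlantedVariant] = []
    for i, (start, end, ref_id, _species) in enumerate(loci):
        b5_seq = chromosome[start - 1 : end]
        tid = f"c{i:05d}_g1_i1"
        tr = list(b5_seq)
        ttd = list(b5_seq)
        glen = len(b5_seq)
        n_var = int(round(glen * variant_density))
        span = glen - 2 * edge_margin
        if span <= 0:
            n_var = 0
        positions: list[int] = []
        attempts = 0
        while len(positions) < n_var and attempts < 50 * max(n_var, 1):
            attempts += 1
            pos = int(rng.integers(edge_margin + 1, glen - edge_margin + 1))
            if all(abs(pos - p) >= min_spacing for p in positions):
                positions.append(pos)
        for pos in sorted(positions):
            b5 = b5_seq[pos - 1]
            others = [b for b in "ACGT" if b != b5]
            group = int(rng.choice([1, 2, 3], p=np.array(group_proportions)))
            if group == 1:
                alt = others[rng.integers(3)]
                tr[pos - 1] = alt
                planted.append(PlantedVariant(tid, pos, "TR", alt, 1, b5))
            elif group == 2:
                alt = others[rng.integers(3)]
                tr[pos - 1] = alt
                ttd[pos - 1] = alt
                planted.append(PlantedVariant(tid, pos, "TR", alt, 2, b5))
                planted.append(PlantedVariant(tid, pos, "TTD", alt, 2, b5))
            else:
                a1, a2 = rng.choice(others, size=2, replace=False)
                tr[pos - 1] = a1
                ttd[pos - 1] = a2
                planted.append(PlantedVariant(tid, pos, "TR", a1, 3, b5))
                planted.append(PlantedVariant(tid, pos, "TTD", a2, 3, b5))
        tr_seq, ttd_seq = "".join(tr), "".join(ttd)
        sets["TR-drought"].append(ReadRecord(id=tid, sequence=tr_seq, library="TR-drought"))
        sets["TR-control"].append(ReadRecord(id=tid, sequence=tr_seq, library="TR-control"))
        ttd_id = f"t{i:05d}_g1_i1"
        sets["TTD-drought"].append(ReadRecord(id=ttd_id, sequence=ttd_seq, library="TTD-drought"))
        sets["TTD-control"].append(ReadRecord(id=ttd_id, sequence=ttd_seq, library="TTD-control"))
    truth.planted_variants = planted
    return sets, planted


def transcript_match_table(
    trio: Mapping[str, Sequence[ReadRecord]],
) -> list[HomologyMatch]:
    """Cross-genotype transcript matches (TR query vs TTD subject) at the
    stringency the transcript filter expects, for position transfer."""
    matches = []
    ttd_by_index = {r.id[1:]: r for r in trio["TTD-drought"]}
    for rec in trio["TR-drought"]:
        mate = ttd_by_index.get(rec.id[1:])
        if mate is None:
            continue
        matches.append(
            HomologyMatch(
                query_id=rec.id,
                subject_id=mate.id,
                pident=99.5,
                align_len=len(rec.sequence),
                qstart=1,
                qend=len(rec.sequence),
                sstart=1,
                send=len(mate.sequence),
                evalue=0.0,
                bitscore=2000.0,
            )
        )
    return matches


def simulate_transcript_reads(
    chromosome: str,
    truth: SyntheticTruth,
    depth: int = 6,
    read_len: int = 120,
    seed: int = 0,
) -> list[ReadRecord]:
    """Chromosome reads tiled over the planted gene loci at approximately
    uniform depth, for the SNP-calling stage (interior positions see
    ``depth`` overlapping reads; coverage ramps at locus edges)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    step = max(1, read_len // depth)
    reads = []
    j = 0
    for start, end, _ref, _sp in truth.gene_loci:
        offset = int(rng.integers(0, step))
        for s in range(start - 1 + offset, end - read_len + 1, step):
            reads.append(
                ReadRecord(
                    id=f"tread{j:06d}",
                    sequence=chromosome[s : s + read_len],
                    library="snp-tiling",
                )
            )
            j += 1
    return reads
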
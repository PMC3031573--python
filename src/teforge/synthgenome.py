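"""Synthetic genomes with planted TE families and full ground truth.

The generator emulates the structures a de novo TE pipeline must cope
with: families of divergent copies (90-99% identity), 5' truncation (the
typical decay mode of LINEs), structural variants (a lineage of copies
sharing a derived internal deletion), nested insertions, target-site
duplications for class II elements, plus the confounders the pipeline's
filters exist for — long segmental duplications and SSR tracts.  Every
planted event is recorded, so annotations and libraries can be scored
against exact truth without any external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_io import Feature, GenomeSet, Interval, revcomp, write_fasta, write_gff3

log = logging.getLogger("teforge")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FamilySpec:
    """Parameters of one planted TE family."""

    name: str
    order: str = "featureless"  # LTR-retro | LINE | TIR-transposon | MITE | SINE | featureless
    ancestor_length: int = 3000
    ltr_length: int = 0
    tir_length: int = 0
    tsd_length: int = 0
    n_copies: int = 5
    identity_mean: float = 95.0
    identity_sd: float = 1.0
    indel_rate: float = 2e-4
    p_truncation_5p: float = 0.0
    p_nested: float = 0.0
    variants: list = field(default_factory=list)  # [((del_start, del_end), fraction), ...]

    def __post_init__(self):
        for L in (self.ltr_length, self.tir_length, self.tsd_length):
            if L >= self.ancestor_length:
                raise ValueError("feature lengths must be < ancestor_length")
        for p in (self.p_truncation_5p, self.p_nested):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class PlantedCopy:
    """Ground-truth record for one planted TE copy."""

    family: str
    variant: int  # 0 = full-length lineage, i>0 = i-th structural variant
    interval: Interval
    identity: float
    truncated_bp: int
    nested_in: Optional[str] = None
    copy_name: str = ""


@dataclass
class Truth:
    genome: GenomeSet
    copies: list = field(default_factory=list)
    ancestors: dict = field(default_factory=dict)
    non_te: list = field(default_factory=list)  # (kind, Interval)

    def truth_intervals(self) -> list:
        return [c.interval for c in self.copies]

    def to_gff3(self, path):
        feats = [
            Feature(
                interval=c.interval,
                type="transposable_element",
                attributes={
                    "ID": c.copy_name,
                    "family": c.family,
                    "variant": c.variant,
                    "identity": f"{c.identity:.1f}",
                    "truncated_bp": c.truncated_bp,
                    **({"nested_in": c.nested_in} if c.nested_in else {}),
                },
            )
            for c in self.copies
        ]
        feats += [
            Feature(interval=iv, type=kind, attributes={"ID": f"{kind}{i}"})
            for i, (kind, iv) in enumerate(self.non_te)
        ]
        write_gff3(feats, path, sequence_lengths=self.genome.lengths)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_ancestor(spec: FamilySpec, rng: np.random.Generator) -> str:
    """Ancestral element with the order's terminal structure: identical
    LTRs at both ends, terminal inverted repeats, a 3' polyA tail for
    LINEs and SINEs, or plain sequence for featureless (Helitron-like)
    families."""
    L = spec.ancestor_length
    if spec.order == "LTR-retro":
        ltr = random_sequence(rng, spec.ltr_length)
        internal = random_sequence(rng, L - 2 * spec.ltr_length)
        return ltr + internal + ltr
    if spec.order in ("TIR-transposon", "MITE"):
        tir = random_sequence(rng, spec.tir_length)
        internal = random_sequence(rng, L - 2 * spec.tir_length)
        return tir + internal + revcomp(tir)
    if spec.order in ("LINE", "SINE"):
        return random_sequence(rng, L - 15) + "A" * 15
    return random_sequence(rng, L)


def mutate(
    seq: str, target_identity: float, indel_rate: float, rng: np.random.Generator
) -> str:
    """Substitutions at rate (100 - identity)/100 plus indels at
    ``indel_rate`` per bp with geometric(mean 3) lengths."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    p_sub = max(0.0, (100.0 - target_identity) / 100.0)
    sub_pos = np.flatnonzero(rng.random(arr.size) < p_sub)
    for i in sub_pos:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    out = arr.tobytes().decode()
    n_indels = rng.binomial(len(out), indel_rate)
    for _ in range(n_indels):
        pos = int(rng.integers(0, max(1, len(out))))
        size = int(rng.geometric(1 / 3.0))
        if rng.random() < 0.5:
            out = out[:pos] + random_sequence(rng, size) + out[pos:]
        else:
            out = out[:pos] + out[pos + size :]
    return out


def _realize_copy(spec: FamilySpec, ancestor: str, rng: np.random.Generator):
    """One mutated copy: variant deletion, 5' truncation, divergence."""
    variant = 0
    seq = ancestor
    if spec.variants:
        u = rng.random()
        acc = 0.0
        for vi, ((ds, de), frac) in enumerate(spec.variants, start=1):
            acc += frac
            if u < acc:
                seq = seq[:ds] + seq[de:]
                variant = vi
                break
    truncated = 0
    if rng.random() < spec.p_truncation_5p:
        truncated = int(rng.integers(1, max(2, int(len(seq) * 0.8))))
        seq = seq[truncated:]
    identity = float(np.clip(rng.normal(spec.identity_mean, spec.identity_sd), 85.0, 100.0))
    seq = mutate(seq, identity, spec.indel_rate, rng)
    return seq, variant, identity, truncated


def plant_copies(
    genome_background: GenomeSet,
    specs: list,
    rng: np.random.Generator,
    min_spacing: int = 1000,
) -> Truth:
    """Insert mutated copies of each family into the background.

    Copies are inserted at random positions (with a minimum spacing between
    insertion points in background coordinates); with probability
    ``p_nested`` a copy is instead inserted inside an already placed copy
    of another family.  Class II copies get a target-site duplication
    (duplicated insertion-site flank).  All events are recorded.
    """
    truth = Truth(genome=GenomeSet(genome_background))
    ancestors = {}
    for spec in specs:
        ancestors[spec.name] = make_ancestor(spec, rng)
    truth.ancestors = ancestors
    seq_ids = sorted(truth.genome)
    # draw all (family, copy) jobs, shuffle for interleaved placement
    jobs = []
    for spec in specs:
        for i in range(spec.n_copies):
            jobs.append((spec, i))
    order = rng.permutation(len(jobs))
    used_points: dict = {name: [] for name in seq_ids}
    counter = 0
    for idx in order:
        spec, _ = jobs[idx]
        seq, variant, identity, truncated = _realize_copy(spec, ancestors[spec.name], rng)
        if not seq:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        placed_seq = seq if strand == "+" else revcomp(seq)
        tsd = ""
        nest_parent = None
        # choose insertion point
        candidates = [c for c in truth.copies if c.family != spec.name and len(c.interval) > 2 * len(seq)]
        if spec.p_nested > 0 and candidates and rng.random() < spec.p_nested:
            host = candidates[int(rng.integers(0, len(candidates)))]
            margin = len(host.interval) // 4
            pos = int(
                rng.integers(host.interval.start + margin, host.interval.end - margin)
            )
            seq_id = host.interval.seq_id
            nest_parent = host.copy_name
        else:
            seq_id = seq_ids[int(rng.integers(0, len(seq_ids)))]
            L = len(truth.genome[seq_id])
            for _ in range(500):
                pos = int(rng.integers(min_spacing, max(min_spacing + 1, L - min_spacing)))
                if any(abs(pos - p) < min_spacing for p in used_points[seq_id]):
                    continue
                # unrecorded nesting is not allowed: stay clear of planted copies
                if _inside_any(truth, seq_id, pos, min_spacing):
                    continue
                break
            else:
                raise ValueError(
                    "could not place copy: background too short for the requested copies"
                )
            used_points[seq_id].append(pos)
        if spec.tsd_length > 0:
            tsd = truth.genome[seq_id][pos : pos + spec.tsd_length]
        # TSD flanks the element: ...[site-copy][TE][site]... after insertion
        insert = tsd + placed_seq
        te_offset = len(tsd)
        g = truth.genome[seq_id]
        truth.genome[seq_id] = g[:pos] + insert + g[pos:]
        shift = len(insert)
        # shift previously recorded intervals
        for c in truth.copies:
            if c.interval.seq_id != seq_id:
                continue
            if c.interval.start >= pos:
                c.interval = c.interval.shifted(shift)
            elif c.interval.start < pos < c.interval.end:
                c.interval = Interval(
                    seq_id, c.interval.start, c.interval.end + shift, c.interval.strand
                )
        for i, (kind, iv) in enumerate(truth.non_te):
            if iv.seq_id == seq_id and iv.start >= pos:
                truth.non_te[i] = (kind, iv.shifted(shift))
        used_points[seq_id] = [p + shift if p >= pos else p for p in used_points[seq_id]]
        copy_name = f"{spec.name}_c{counter}"
        counter += 1
        truth.copies.append(
            PlantedCopy(
                family=spec.name,
                variant=variant,
                interval=Interval(
                    seq_id, pos + te_offset, pos + te_offset + len(placed_seq), strand
                ),
                identity=identity,
                truncated_bp=truncated,
                nested_in=nest_parent,
                copy_name=copy_name,
            )
        )
    truth.copies.sort(key=lambda c: (c.interval.seq_id, c.interval.start))
    return truth


def _inside_any(truth: Truth, seq_id: str, pos: int, margin: int = 0) -> bool:
    for c in truth.copies:
        iv = c.interval
        if iv.seq_id == seq_id and iv.start - margin < pos < iv.end + margin:
            return True
    for _, iv in truth.non_te:
        if iv.seq_id == seq_id and iv.start - margin < pos < iv.end + margin:
            return True
    return False


def add_confounders(
    truth: Truth,
    rng: np.random.Generator,
    n_segdups: int = 0,
    n_ssr_tracts: int = 0,
    segdup_length: int = 25_000,
    ssr_length: int = 300,
) -> Truth:
    """Insert long two-copy segmental duplications and SSR tracts,
    recorded as non-TE truth; the pipeline's filters should reject both."""
    seq_ids = sorted(truth.genome)
    for _ in range(n_segdups):
        src_id = seq_ids[int(rng.integers(0, len(seq_ids)))]
        g = truth.genome[src_id]
        if len(g) < segdup_length + 1000:
            continue
        s = int(rng.integers(0, len(g) - segdup_length))
        block = g[s : s + segdup_length]
        dst_id = seq_ids[int(rng.integers(0, len(seq_ids)))]
        for _ in range(200):
            pos = int(rng.integers(0, len(truth.genome[dst_id])))
            if (dst_id != src_id or not (s <= pos <= s + segdup_length)) and not _inside_any(
                truth, dst_id, pos
            ):
                break
        # record the source before inserting so the shift logic adjusts it
        truth.non_te.append(
            ("segmental_duplication", Interval(src_id, s, s + segdup_length, "+"))
        )
        _insert_block(truth, dst_id, pos, block, "segmental_duplication")
    for _ in range(n_ssr_tracts):
        motif = random_sequence(rng, int(rng.integers(1, 7)))
        tract = (motif * (ssr_length // len(motif) + 1))[:ssr_length]
        dst_id = seq_ids[int(rng.integers(0, len(seq_ids)))]
        for _ in range(200):
            pos = int(rng.integers(0, len(truth.genome[dst_id])))
            if not _inside_any(truth, dst_id, pos):
                break
        _insert_block(truth, dst_id, pos, tract, "SSR_tract")
    return truth


def _insert_block(truth: Truth, seq_id: str, pos: int, block: str, kind: str):
    g = truth.genome[seq_id]
    truth.genome[seq_id] = g[:pos] + block + g[pos:]
    shift = len(block)
    for c in truth.copies:
        if c.interval.seq_id != seq_id:
            continue
        if c.interval.start >= pos:
            c.interval = c.interval.shifted(shift)
        elif c.interval.start < pos < c.interval.end:
            c.interval = Interval(seq_id, c.interval.start, c.interval.end + shift, c.interval.strand)
    for i, (k, iv) in enumerate(truth.non_te):
        if iv.seq_id == seq_id and iv.start >= pos:
            truth.non_te[i] = (k, iv.shifted(shift))
    truth.non_te.append((kind, Interval(seq_id, pos, pos + shift, "+")))


# ---------------------------------------------------------------------------
# scenarios


def default_specs() -> list:
    """The default study conditions: eight families spanning the main TE
    orders, 5-20 copies each at 92-99% identity, two families with a
    structural-variant lineage, one featureless family with three full
    copies.

    Identities are per-copy divergence from the ancestor; two copies at
    identity i each are ~(100 - 2*(100-i))% identical to one another, so
    these means put pairwise copy identity in the 92-98% band the
    interspersed-repeat alignment step assumes.
    """
    return [
        FamilySpec("fam1-gypsy", "LTR-retro", 4000, ltr_length=300, n_copies=8,
                   identity_mean=96.5, identity_sd=0.8, p_truncation_5p=0.2, p_nested=0.1),
        FamilySpec("fam2-copia", "LTR-retro", 5000, ltr_length=250, n_copies=12,
                   identity_mean=97, identity_sd=0.7,
                   variants=[((1500, 3000), 0.5)]),
        FamilySpec("fam3-mariner", "TIR-transposon", 2500, tir_length=30, tsd_length=8,
                   n_copies=10, identity_mean=96, identity_sd=0.8,
                   p_truncation_5p=0.1, p_nested=0.1),
        FamilySpec("fam4-mite", "MITE", 400, tir_length=30, tsd_length=4, n_copies=20,
                   identity_mean=98, identity_sd=0.7),
        FamilySpec("fam5-jockey", "LINE", 3500, n_copies=10, identity_mean=96,
                   identity_sd=1.0, p_truncation_5p=0.5),
        FamilySpec("fam6-sine", "SINE", 300, n_copies=15, identity_mean=97.5, identity_sd=0.8),
        FamilySpec("fam7-helitron", "featureless", 3000, n_copies=3,
                   identity_mean=98.5, identity_sd=0.5),
        FamilySpec("fam8-hat", "TIR-transposon", 3000, tir_length=25, tsd_length=8,
                   n_copies=10, identity_mean=96.5, identity_sd=0.8,
                   variants=[((800, 1700), 0.4)]),
    ]


def eligible_full_length_families(
    truth: Truth, min_pair_identity: float = 92.0, min_copies: int = 3
) -> set:
    """Families a de novo pipeline can be expected to recover in full:
    those with >= 3 full-length (untruncated, non-variant) copies whose
    pairwise identity — approximately 100 minus the summed divergences of
    the two copies from the ancestor — is at least ``min_pair_identity``."""
    out = set()
    per_family: dict = {}
    for c in truth.copies:
        if c.variant == 0 and c.truncated_bp == 0:
            per_family.setdefault(c.family, []).append(c.identity)
    for fam, idents in per_family.items():
        idents = sorted(idents, reverse=True)
        good = [
            i
            for i in idents
            if sum(
                1
                for j in idents
                if j is not i and 100 - ((100 - i) + (100 - j)) >= min_pair_identity
            )
            >= min_copies - 1
        ]
        if len(good) >= min_copies:
            out.add(fam)
    return out


def simulate(
    seed: int,
    specs: Optional[list] = None,
    background_length: int = 250_000,
    n_sequences: int = 2,
    n_segdups: int = 1,
    n_ssr_tracts: int = 3,
) -> Truth:
    """Generate the default synthetic genome: background sequences, planted
    families, and confounders.  Same seed -> byte-identical output."""
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = default_specs()
    per_seq = background_length // n_sequences
    background = GenomeSet(
        {f"chr{i+1}": random_sequence(rng, per_seq) for i in range(n_sequences)}
    )
    truth = plant_copies(background, specs, rng)
    truth = add_confounders(truth, rng, n_segdups=n_segdups, n_ssr_tracts=n_ssr_tracts)
    return truth


def write_outputs(truth: Truth, out_dir, scenario: Optional[dict] = None):
    """Write genome.fa, truth.gff3, ancestors.fa and scenario.json."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    write_fasta(truth.genome, os.path.join(out_dir, "genome.fa"))
    truth.to_gff3(os.path.join(out_dir, "truth.gff3"))
    write_fasta(truth.ancestors, os.path.join(out_dir, "ancestors.fa"))
    if scenario is not None:
        with open(os.path.join(out_dir, "scenario.json"), "w") as fh:
            json.dump(scenario, fh, indent=2)
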
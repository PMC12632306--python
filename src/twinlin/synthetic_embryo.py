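"""Forward simulation of early embryogenesis, twinning, and sequencing readouts.

The embryo grows as a complete binary cell-division tree from the zygote.
Each daughter cell acquires Poisson(mutation_rate) new early embryonic
mutations (EEMs) at birth, which are inherited by all of its descendants —
an irreversible endogenous lineage barcode.  Pre-zygotic de novo variants
sit on the zygote itself and are therefore heterozygous in every somatic
cell (true VAF 0.5 everywhere).

Twinning partitions cells of one embryonic generation into two founder
sets.  Tissues are founded by a progenitor bottleneck sampled from each
twin's leaf cells; the true cell fraction of a mutation in a tissue is the
carrier fraction among its progenitors, and sequencing draws
Poisson-distributed depths with binomial alternate-read counts (symmetric
substitution error split equally among the three non-reference bases).
Monochorionic cord bloods are linear mixtures of the two twins'
hematopoietic pools.  Single-cell readouts apply locus dropout, allelic
dropout, and false-positive calls to the true leaf genotypes.

Every stochastic step is driven by an explicit seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anchor_model import classify_category
from .sc_lineage import ALT, MISSING, REF, ScGenotypeMatrix, ScParams
from .variant_io import VariantTable, make_variant_id

# virtual genome: 23 chromosomes, ~3.0 Gb total
CHROM_LENGTHS = {
    **{f"chr{i}": length for i, length in enumerate(
        [248_000_000, 242_000_000, 198_000_000, 190_000_000, 182_000_000,
         171_000_000, 159_000_000, 145_000_000, 138_000_000, 134_000_000,
         135_000_000, 133_000_000, 114_000_000, 107_000_000, 102_000_000,
         90_000_000, 83_000_000, 80_000_000, 59_000_000, 64_000_000,
         47_000_000, 51_000_000], start=1)},
    "chrX": 156_000_000,
}
GENOME_SIZE = sum(CHROM_LENGTHS.values())
_CHROM_NAMES = list(CHROM_LENGTHS)
_CHROM_STARTS = np.concatenate([[0], np.cumsum([CHROM_LENGTHS[c] for c in _CHROM_NAMES])])

TISSUES = ("buccal", "cord_blood", "umbilical_cord", "placenta_patch", "pbmc")
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationParams:
    """Study conditions of the forward simulation.

    mutation_rate: expected new EEMs per daughter cell per division.
    n_generations: depth of the complete binary division tree.
    denovo_count: heterozygous pre-zygotic variants on the zygote.
    wgs_depth / targeted_depth / parental_depth: mean sequencing depths.
    seq_error: per-base substitution error rate.
    detection_min_alt / detection_min_vaf: variant detection rule.
    """

    mutation_rate: float = 1.2
    n_generations: int = 12
    denovo_count: int = 68
    wgs_depth: float = 60.0
    targeted_depth: float = 700.0
    parental_depth: float = 30.0
    seq_error: float = 0.001
    detection_min_alt: int = 3
    detection_min_vaf: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be non-negative")
        if self.n_generations < 1:
            raise ValueError("n_generations must be at least 1")
        if min(self.wgs_depth, self.targeted_depth, self.parental_depth) <= 0:
            raise ValueError("depths must be positive")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must lie in [0, 0.5)")
        if self.denovo_count < 0:
            raise ValueError("denovo_count must be non-negative")


# -- lineage tree ---------------------------------------------------------


@dataclass
class LineageTree:
    """Complete binary division tree in heap order (zygote = node 1).

    Node ``v`` sits at generation ``v.bit_length() - 1``; its daughters are
    ``2v`` and ``2v + 1``.  ``node_mutations`` maps a node to the mutation
    ids acquired at its birth (absent keys mean none); a leaf's genotype is
    the union of mutations along its root path.
    """

    n_generations: int
    node_mutations: dict[int, list[str]]

    @property
    def n_leaves(self) -> int:
        return 1 << self.n_generations

    def generation(self, node: int) -> int:
        return int(node).bit_length() - 1

    def cells_at(self, generation: int) -> np.ndarray:
        return np.arange(1 << generation, 1 << (generation + 1), dtype=np.int64)

    def leaves_of(self, node: int) -> np.ndarray:
        lo, hi = self.leaf_span(node)
        return np.arange(lo, hi, dtype=np.int64)

    def leaf_span(self, node: int) -> tuple[int, int]:
        shift = self.n_generations - self.generation(node)
        return node << shift, (node + 1) << shift

    def root_path(self, node: int) -> list[int]:
        path = []
        while node >= 1:
            path.append(node)
            node >>= 1
        return path[::-1]

    def genotype(self, leaf: int) -> frozenset:
        muts = []
        for node in self.root_path(leaf):
            muts.extend(self.node_mutations.get(node, ()))
        return frozenset(muts)


def _draw_variant_ids(n: int, rng: np.random.Generator, taken: set | None = None) -> pd.DataFrame:
    """Unique variant sites drawn uniformly from the virtual genome."""
    taken = set() if taken is None else set(taken)
    gpos_list: list[int] = []
    while len(gpos_list) < n:
        draw = rng.integers(0, GENOME_SIZE, size=n - len(gpos_list))
        for g in draw:
            g = int(g)
            if g not in taken:
                taken.add(g)
                gpos_list.append(g)
    gpos = np.array(gpos_list, dtype=np.int64)
    ci = np.searchsorted(_CHROM_STARTS, gpos, side="right") - 1
    pos = gpos - _CHROM_STARTS[ci].astype(np.int64) + 1
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    df = pd.DataFrame(
        {
            "chrom": [_CHROM_NAMES[int(c)] for c in ci],
            "pos": pos.astype(int),
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
            "gpos": gpos,
        }
    )
    df.insert(
        0,
        "variant",
        [
            make_variant_id(c, int(p), r, a)
            for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
        ],
    )
    return df


def simulate_lineage(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[LineageTree, pd.DataFrame]:
    """Grow the division tree and its mutation catalog.

    Returns the tree and a catalog DataFrame indexed by variant id with
    columns ``chrom, pos, ref, alt, origin_node, origin_class`` —
    ``denovo`` mutations originate at the zygote (node 1), ``eem``
    mutations at the node where they arose.
    """
    rng = rng or np.random.default_rng(params.seed)
    n_nodes = (1 << (params.n_generations + 1)) - 1
    non_root = np.arange(2, n_nodes + 1, dtype=np.int64)
    eem_counts = rng.poisson(params.mutation_rate, size=len(non_root))
    total = params.denovo_count + int(eem_counts.sum())
    sites = _draw_variant_ids(total, rng)

    origin_nodes = np.concatenate(
        [np.ones(params.denovo_count, dtype=np.int64), np.repeat(non_root, eem_counts)]
    )
    origin_class = np.array(
        ["denovo"] * params.denovo_count + ["eem"] * int(eem_counts.sum())
    )
    catalog = sites.set_index("variant").drop(columns="gpos")
    catalog["origin_node"] = origin_nodes
    catalog["origin_class"] = origin_class

    node_mutations: dict[int, list[str]] = {}
    ids = catalog.index.to_numpy()
    for node, vid in zip(origin_nodes, ids):
        node_mutations.setdefault(int(node), []).append(vid)
    tree = LineageTree(params.n_generations, node_mutations)
    return tree, catalog


# -- twinning -------------------------------------------------------------


@dataclass
class TwinPartition:
    """Founder cells of each twin at the split generation, with ground truth.

    ``l1_node`` is the ancestor cell defining the dominant lineage L1;
    ``true_a`` / ``true_b`` are the leaf-level fractions of Twin 1 / Twin 2
    descending from it (Twin 1 ordered so that a >= b).
    """

    twins: dict[str, np.ndarray]
    mode: str
    split_generation: int
    l1_node: int
    true_a: float
    true_b: float
    n_generations: int

    def leaves(self, twin_id: str, tree: LineageTree) -> np.ndarray:
        spans = [tree.leaf_span(int(f)) for f in self.twins[twin_id]]
        return np.concatenate([np.arange(lo, hi, dtype=np.int64) for lo, hi in spans])


def _l1_leaf_fraction(tree: LineageTree, leaves_sorted: np.ndarray, node: int) -> float:
    lo, hi = tree.leaf_span(node)
    n = np.searchsorted(leaves_sorted, hi) - np.searchsorted(leaves_sorted, lo)
    return float(n) / len(leaves_sorted)


def apply_twinning(
    tree: LineageTree,
    mode: str,
    split_generation: int,
    allocation: float | None = None,
    contributions: tuple[float, float] | None = None,
    founders_per_twin: int | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> TwinPartition:
    """Partition one embryonic generation into the two twins' founder sets.

    * ``para``: the two daughters of a randomly chosen ancestor one
      generation above the split found Twin 1 and Twin 2; their lineages
      segregate completely, so (a, b) = (1, 0).
    * ``sub``: Twin 1 buds off as a single founder cell at the split
      generation; Twin 2 takes every other contemporaneous cell (a = 1,
      0 < b < 1 by construction).
    * ``full``: cells at the split generation are partitioned at random
      with Twin-1 share ``allocation``; alternatively ``contributions``
      = (a, b) builds founder sets realizing those L1 fractions exactly.
    """
    rng = rng or np.random.default_rng(seed)
    s = split_generation
    if not 1 <= s < tree.n_generations:
        raise ValueError("split_generation must lie in [1, n_generations)")
    cells = tree.cells_at(s)

    if mode == "para":
        anc = int(rng.choice(tree.cells_at(s - 1)))
        f1, f2 = 2 * anc, 2 * anc + 1
        twins = {"twin1": np.array([f1]), "twin2": np.array([f2])}
        return TwinPartition(twins, mode, s, f1, 1.0, 0.0, tree.n_generations)

    if mode == "sub":
        c = int(rng.choice(cells))
        rest = cells[cells != c]
        l1 = c >> (s - 1)  # generation-1 ancestor of the budding founder
        twins = {"twin1": np.array([c]), "twin2": rest}
        part = TwinPartition(twins, mode, s, l1, 1.0, 0.0, tree.n_generations)
        leaves2 = np.sort(part.leaves("twin2", tree))
        part.true_b = _l1_leaf_fraction(tree, leaves2, l1)
        return part

    if mode != "full":
        raise ValueError(f"unknown twinning mode: {mode}")

    left = cells[cells < (3 << (s - 1))]  # descendants of node 2
    right = cells[cells >= (3 << (s - 1))]
    if contributions is not None:
        a_t, b_t = contributions
        if not (0 <= b_t <= 1 and 0 <= a_t <= 1):
            raise ValueError("contributions must lie in [0, 1]")
        k = founders_per_twin or max(2, len(cells) // 4)
        n1 = int(round(a_t * k))
        n2 = int(round(b_t * k))
        if n1 + n2 > len(left) or (k - n1) + (k - n2) > len(right):
            raise ValueError("not enough cells for the requested contributions")
        pick_l = rng.choice(left, size=n1 + n2, replace=False)
        pick_r = rng.choice(right, size=(k - n1) + (k - n2), replace=False)
        t1 = np.sort(np.concatenate([pick_l[:n1], pick_r[: k - n1]]))
        t2 = np.sort(np.concatenate([pick_l[n1:], pick_r[k - n1 :]]))
    else:
        if allocation is None or not 0 < allocation < 1:
            raise ValueError("mode=full requires allocation in (0, 1) or contributions")
        n1 = int(round(allocation * len(cells)))
        n1 = min(max(n1, 1), len(cells) - 1)
        perm = rng.permutation(cells)
        t1, t2 = np.sort(perm[:n1]), np.sort(perm[n1:])

    twins = {"twin1": t1, "twin2": t2}
    part = TwinPartition(twins, "full", s, 2, 0.0, 0.0, tree.n_generations)
    l1_candidates = (2, 3)
    best = None
    for node in l1_candidates:
        fa = _l1_leaf_fraction(tree, np.sort(part.leaves("twin1", tree)), node)
        fb = _l1_leaf_fraction(tree, np.sort(part.leaves("twin2", tree)), node)
        if best is None or fa + fb > best[1] + best[2]:
            best = (node, fa, fb)
    l1, a, b = best
    if a < b:  # Twin 1 carries the higher L1 contribution by definition
        twins = {"twin1": twins["twin2"], "twin2": twins["twin1"]}
        a, b = b, a
    return TwinPartition(twins, "full", s, int(l1), float(a), float(b), tree.n_generations)


def apply_triplet_twinning(
    tree: LineageTree,
    first_split: int = 4,
    second_split: int = 6,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[TwinPartition, str]:
    """Two consecutive sub-mode twinning events producing a triplet.

    The first budding founder separates the (triplet1, triplet2) precursor
    from triplet3; a second bud within that precursor separates triplet1
    from triplet2, so the true topology is ((triplet1, triplet2), triplet3).
    """
    rng = rng or np.random.default_rng(seed)
    if not 1 <= first_split < second_split < tree.n_generations:
        raise ValueError("need 1 <= first_split < second_split < n_generations")
    c1 = int(rng.choice(tree.cells_at(first_split)))
    t3 = tree.cells_at(first_split)
    t3 = t3[t3 != c1]
    sub = np.arange(
        c1 << (second_split - first_split), (c1 + 1) << (second_split - first_split),
        dtype=np.int64,
    )
    c2 = int(rng.choice(sub))
    t2 = sub[sub != c2]
    part = TwinPartition(
        {"triplet1": np.array([c2]), "triplet2": t2, "triplet3": t3},
        "triplet", second_split, c1 >> (first_split - 1) if first_split > 1 else c1,
        1.0, 0.0, tree.n_generations,
    )
    return part, "((triplet1,triplet2),triplet3);"


# -- tissue sampling and sequencing ---------------------------------------


@dataclass
class TissueSample:
    sample_id: str
    individual: str
    tissue: str
    cell_fraction: pd.Series  # variant id -> true carrier fraction in [0, 1]
    progenitors: np.ndarray | None = None  # leaf cells backing the sample
    l1_fraction: float | None = None  # realized L1 contribution to this tissue


def _carrier_fractions(
    tree: LineageTree, catalog: pd.DataFrame, progenitors: np.ndarray
) -> pd.Series:
    """True cell fraction of every catalog mutation among the progenitors."""
    leaves = np.sort(progenitors)
    nodes = catalog["origin_node"].to_numpy(dtype=np.int64)
    gens = np.floor(np.log2(nodes)).astype(np.int64)
    shift = tree.n_generations - gens
    lo = nodes << shift
    hi = (nodes + 1) << shift
    counts = np.searchsorted(leaves, hi) - np.searchsorted(leaves, lo)
    frac = counts / len(progenitors)
    frac[(catalog["origin_class"] == "denovo").to_numpy()] = 1.0
    return pd.Series(frac, index=catalog.index)


def sample_tissue(
    tree: LineageTree,
    catalog: pd.DataFrame,
    partition: TwinPartition,
    twin_id: str,
    tissue: str,
    n_progenitors: int,
    rng: np.random.Generator,
) -> TissueSample:
    """Found a tissue by a progenitor bottleneck from the twin's leaf cells."""
    if twin_id not in partition.twins:
        raise ValueError(f"unknown twin: {twin_id}")
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue: {tissue}")
    if n_progenitors < 1:
        raise ValueError("n_progenitors must be positive")
    leaves = partition.leaves(twin_id, tree)
    replace = n_progenitors > len(leaves)
    prog = rng.choice(leaves, size=n_progenitors, replace=replace)
    frac = _carrier_fractions(tree, catalog, prog)
    keep = (frac > 0) | (catalog["origin_class"] == "denovo").to_numpy()
    prog_sorted = np.sort(prog)
    lo, hi = tree.leaf_span(partition.l1_node)
    l1_frac = float(
        (np.searchsorted(prog_sorted, hi) - np.searchsorted(prog_sorted, lo)) / n_progenitors
    )
    return TissueSample(
        f"{twin_id}_{tissue}", twin_id, tissue, frac[keep], prog, l1_frac
    )


def sequence_counts(
    fractions: pd.Series,
    mean_depth: float,
    params: SimulationParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson depths and binomial alt counts for true cell fractions.

    The read-level alt probability is VAF*(1-e) + (1-VAF)*e/3 with
    VAF = fraction / 2 (heterozygous mutations).
    """
    vaf_true = np.clip(fractions.to_numpy(dtype=float) / 2.0, 0.0, 0.5)
    e = params.seq_error
    p = vaf_true * (1 - e) + (1 - vaf_true) * e / 3.0
    depth = rng.poisson(mean_depth, size=len(vaf_true))
    alt = rng.binomial(depth, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    return pd.DataFrame(
        {"depth": depth, "alt": alt, "vaf": vaf}, index=fractions.index
    )


def sample_and_sequence(
    tree: LineageTree,
    catalog: pd.DataFrame,
    partition: TwinPartition,
    twin_id: str,
    tissue: str,
    n_progenitors: int,
    depth_regime: str,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[TissueSample, pd.DataFrame]:
    """Bottleneck-found a tissue and sequence its carried variants."""
    rng = rng or np.random.default_rng(params.seed)
    if depth_regime not in ("wgs", "targeted"):
        raise ValueError(f"unknown depth regime: {depth_regime}")
    sample = sample_tissue(tree, catalog, partition, twin_id, tissue, n_progenitors, rng)
    depth = params.wgs_depth if depth_regime == "wgs" else params.targeted_depth
    reads = sequence_counts(sample.cell_fraction, depth, params, rng)
    return sample, reads


def mix_cord_blood(
    blood1: TissueSample,
    blood2: TissueSample,
    f: float,
    chorionicity: str,
) -> tuple[TissueSample, TissueSample]:
    """Mix the two twins' hematopoietic pools through a shared placenta.

    ``f`` is the fraction of the common pool derived from Twin 1's
    hematopoietic lineage.  Dichorionic twins do not exchange blood and the
    inputs are returned unchanged; monochorionic twins draw both cord
    bloods from the single mixed pool.
    """
    if not 0 <= f <= 1:
        raise ValueError("mixing fraction f must lie in [0, 1]")
    if chorionicity not in ("monochorionic", "dichorionic"):
        raise ValueError(f"unknown chorionicity: {chorionicity}")
    if chorionicity == "dichorionic":
        return blood1, blood2
    union = blood1.cell_fraction.index.union(blood2.cell_fraction.index)
    f1 = blood1.cell_fraction.reindex(union, fill_value=0.0)
    f2 = blood2.cell_fraction.reindex(union, fill_value=0.0)
    mixed = f * f1 + (1 - f) * f2
    l1 = None
    if blood1.l1_fraction is not None and blood2.l1_fraction is not None:
        l1 = f * blood1.l1_fraction + (1 - f) * blood2.l1_fraction
    out1 = TissueSample(blood1.sample_id, blood1.individual, blood1.tissue, mixed.copy(), None, l1)
    out2 = TissueSample(blood2.sample_id, blood2.individual, blood2.tissue, mixed.copy(), None, l1)
    return out1, out2


# -- single cells ----------------------------------------------------------


def simulate_single_cells(
    tree: LineageTree,
    catalog: pd.DataFrame,
    sample: TissueSample,
    sc: ScParams,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    variants: list | None = None,
    cell_prefix: str | None = None,
) -> ScGenotypeMatrix:
    """Amplify and genotype single cells from a tissue's progenitor pool.

    Each cell x variant entry is missing with probability ``locus_dropout``;
    otherwise a true-alt site reads alt with probability 1 - ado_rate and a
    true-ref site reads alt with probability ``fp_rate``.
    """
    rng = rng or np.random.default_rng(seed)
    if sample.progenitors is None:
        raise ValueError("sample has no underlying cell list (mixed or synthetic sample)")
    if variants is None:
        variants = list(sample.cell_fraction.index)
    sub = catalog.loc[variants]
    replace = sc.n_cells > len(sample.progenitors)
    cells = rng.choice(sample.progenitors, size=sc.n_cells, replace=replace)

    nodes = sub["origin_node"].to_numpy(dtype=np.int64)
    gens = np.floor(np.log2(nodes)).astype(np.int64)
    shift = tree.n_generations - gens
    lo = nodes << shift
    hi = (nodes + 1) << shift
    truth = (cells[:, None] >= lo[None, :]) & (cells[:, None] < hi[None, :])

    u_missing = rng.random(truth.shape) < sc.locus_dropout
    u_ado = rng.random(truth.shape) < sc.ado_rate
    u_fp = rng.random(truth.shape) < sc.fp_rate
    obs = np.where(truth, np.where(u_ado, REF, ALT), np.where(u_fp, ALT, REF))
    obs = np.where(u_missing, MISSING, obs).astype(np.int8)

    prefix = cell_prefix or sample.sample_id
    index = [f"{prefix}_c{i:04d}" for i in range(sc.n_cells)]
    data = pd.DataFrame(obs, index=index, columns=variants)
    twin = pd.Series(sample.individual, index=index)
    return ScGenotypeMatrix(data, cell_twin=twin, params=sc)


# -- direct two-lineage VAF generator -------------------------------------


def simulate_pair_vafs(
    a: float,
    b: float,
    n_anchor: int = 10,
    n_counter: int = 10,
    n_subclonal: int = 8,
    n_private: int = 4,
    depth: float = 700.0,
    seq_error: float = 0.001,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """EEM read counts for a twin pair directly under the two-lineage model.

    Anchor EEMs sit at true VAFs (a/2, b/2), counter-anchor EEMs at
    ((1-a)/2, (1-b)/2); sub-lineage EEMs are carried by a random fraction
    of L1 or L2 descendants, and private EEMs by one twin only.  Used for
    parameter-recovery studies where the anchor-cluster size must be
    controlled exactly.
    """
    if not (0 <= b <= a <= 1) or a + b < 1:
        raise ValueError("require 0 <= b <= a <= 1 and a + b >= 1 (L1 dominant)")
    rng = rng or np.random.default_rng(seed)
    rows = []
    for _ in range(n_anchor):
        rows.append(("anchor", a / 2, b / 2))
    for _ in range(n_counter):
        rows.append(("counter", (1 - a) / 2, (1 - b) / 2))
    for _ in range(n_subclonal):
        u = rng.uniform(0.15, 0.6)
        if rng.random() < 0.5:
            rows.append(("sub_l1", u * a / 2, u * b / 2))
        else:
            rows.append(("sub_l2", u * (1 - a) / 2, u * (1 - b) / 2))
    for _ in range(n_private):
        w = rng.uniform(0.2, 0.9)
        if rng.random() < 0.5:
            rows.append(("private1", w / 2, 0.0))
        else:
            rows.append(("private2", 0.0, w / 2))
    df = pd.DataFrame(rows, columns=["cluster", "vaf1_true", "vaf2_true"])
    e = seq_error
    for twin in (1, 2):
        v = df[f"vaf{twin}_true"].to_numpy()
        p = v * (1 - e) + (1 - v) * e / 3.0
        d = rng.poisson(depth, size=len(df))
        alt = rng.binomial(d, p)
        df[f"depth{twin}"] = d
        df[f"alt{twin}"] = alt
        df[f"vaf{twin}"] = np.where(d > 0, alt / np.maximum(d, 1), np.nan)
    return df


# -- cohort ----------------------------------------------------------------

# per-membrane clonal category composition matching the observed cohort:
# monoamniotic twins are almost exclusively full-identical, diamniotic
# twins mostly sub- or para-identical
DEFAULT_CATEGORIES = {
    "MCMA": ["full", "full", "full", "full", "full", "full", "full", "sub"],
    "MCDA": ["para", "para", "sub", "sub", "sub", "sub", "full"],
    "DCDA": ["para", "sub", "sub", "sub", "sub", "sub", "full"],
}


@dataclass
class CohortConfig:
    n_mcma: int = 8
    n_mcda: int = 7
    n_dcda: int = 7
    n_triplets: int = 1
    n_dz: int = 6
    params: SimulationParams = field(default_factory=SimulationParams)
    n_inherited: int = 50
    buccal_progenitors: int = 32
    blood_progenitors: int = 32
    placenta_progenitors: int = 8
    include_blood: bool = True
    mixing_low: float = 0.56
    mixing_high: float = 0.83
    para_splits: tuple[int, int] = (4, 6)  # half-open draw range
    sub_splits: tuple[int, int] = (6, 9)
    full_split: int = 6
    full_a_range: tuple[float, float] = (0.5, 0.85)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = SimulationParams(**raw.pop("params", {}))
        for key in ("para_splits", "sub_splits", "full_a_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(params=params, **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class CohortBundle:
    """Simulated cohort: discovery (WGS) and validation (targeted) tables.

    ``tables`` hold the 60x whole-genome discovery counts including the
    parents; ``targeted`` holds 700x deep-targeted re-sequencing of the
    same candidate sites in the children's tissues, mirroring the
    discovery-then-validation design that the VAF-based model fits rely on.
    """

    tables: dict[str, VariantTable]
    targeted: dict[str, VariantTable]
    metadata: pd.DataFrame
    truth: dict


def _family_categories(config: CohortConfig) -> list[tuple[str, str, str]]:
    """(family id, membrane type, category) for every simulated family."""
    fams = []
    counts = {"MCMA": config.n_mcma, "MCDA": config.n_mcda, "DCDA": config.n_dcda}
    i = 1
    for membrane in ("MCMA", "MCDA", "DCDA"):
        base = DEFAULT_CATEGORIES[membrane]
        for j in range(counts[membrane]):
            fams.append((f"F{i:02d}", membrane, base[j % len(base)]))
            i += 1
    for _ in range(config.n_triplets):
        fams.append((f"F{i:02d}", "DCTA", "triplet"))
        i += 1
    for _ in range(config.n_dz):
        fams.append((f"F{i:02d}", "DZ", "dizygotic"))
        i += 1
    return fams


def _count_block(family: str, sid: str, reads: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": family,
            "variant": reads.index,
            "sample": sid,
            "depth": reads["depth"].astype(int).to_numpy(),
            "alt": reads["alt"].astype(int).to_numpy(),
        }
    )


def _inherited_block(
    config: CohortConfig, rng: np.random.Generator, taken: set
) -> pd.DataFrame:
    inh = _draw_variant_ids(config.n_inherited, rng, taken)
    inh["parent"] = np.where(rng.random(len(inh)) < 0.5, "mother", "father")
    return inh


def _simulate_mz_family(
    family: str, membrane: str, category: str, config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[VariantTable, list[dict], dict]:
    p = config.params
    tree, catalog = simulate_lineage(p, rng=rng)
    if category == "para":
        s = int(rng.integers(*config.para_splits))
        part = apply_twinning(tree, "para", s, rng=rng)
    elif category == "sub":
        s = int(rng.integers(*config.sub_splits))
        part = apply_twinning(tree, "sub", s, rng=rng)
    else:
        a_t = float(rng.uniform(*config.full_a_range))
        part = apply_twinning(
            tree, "full", config.full_split, contributions=(a_t, a_t), rng=rng
        )

    samples: dict[str, TissueSample] = {}
    for twin in ("twin1", "twin2"):
        samples[f"{twin}_buccal"] = sample_tissue(
            tree, catalog, part, twin, "buccal", config.buccal_progenitors, rng
        )
    blood_f1 = None  # per cord-blood sample: fraction from Twin 1's lineage
    if config.include_blood:
        b1 = sample_tissue(
            tree, catalog, part, "twin1", "cord_blood", config.blood_progenitors, rng
        )
        b2 = sample_tissue(
            tree, catalog, part, "twin2", "cord_blood", config.blood_progenitors, rng
        )
        if membrane in ("MCMA", "MCDA"):
            major = float(rng.uniform(config.mixing_low, config.mixing_high))
            f = major if rng.random() < 0.5 else 1.0 - major
            b1, b2 = mix_cord_blood(b1, b2, f, "monochorionic")
            blood_f1 = {"twin1_cord_blood": f, "twin2_cord_blood": f}
        else:
            b1, b2 = mix_cord_blood(b1, b2, 1.0, "dichorionic")
            blood_f1 = {"twin1_cord_blood": 1.0, "twin2_cord_blood": 0.0}
        samples["twin1_cord_blood"] = b1
        samples["twin2_cord_blood"] = b2

    inh = _inherited_block(config, rng, set())
    union = sorted(
        set().union(*(set(s.cell_fraction.index) for s in samples.values()))
    )
    count_frames = []
    targeted_frames = []
    meta_rows = []
    # children: 60x WGS discovery plus 700x targeted validation
    for name, sample in samples.items():
        frac = sample.cell_fraction.reindex(union, fill_value=0.0)
        frac = pd.concat([frac, pd.Series(1.0, index=inh["variant"])])
        reads = sequence_counts(frac, p.wgs_depth, p, rng)
        sid = f"{family}_{name}"
        count_frames.append(_count_block(family, sid, reads))
        reads_t = sequence_counts(frac, p.targeted_depth, p, rng)
        targeted_frames.append(_count_block(family, sid, reads_t))
        meta_rows.append(
            {
                "sample": sid, "family": family,
                "individual": f"{family}_{sample.individual}",
                "tissue": sample.tissue, "zygosity": "MZ", "membrane": membrane,
            }
        )
    # parents: inherited variants het in the transmitting parent
    for parent in ("mother", "father"):
        frac_child = pd.Series(0.0, index=pd.Index(union))
        own = pd.Series(
            np.where(inh["parent"].to_numpy() == parent, 1.0, 0.0),
            index=inh["variant"],
        )
        frac = pd.concat([frac_child, own])
        reads = sequence_counts(frac, p.parental_depth, p, rng)
        sid = f"{family}_{parent}"
        count_frames.append(_count_block(family, sid, reads))
        meta_rows.append(
            {
                "sample": sid, "family": family, "individual": sid,
                "tissue": "pbmc", "zygosity": "parent", "membrane": membrane,
            }
        )

    all_variants = list(union) + list(inh["variant"])
    flags = pd.DataFrame(False, index=pd.Index(all_variants), columns=["mother", "father"])
    for _, row in inh.iterrows():
        flags.loc[row["variant"], row["parent"]] = True

    df = pd.concat(count_frames, ignore_index=True)
    df["vaf"] = np.where(df["depth"] > 0, df["alt"] / df["depth"].clip(lower=1), np.nan)
    table = VariantTable(df, parent_flags=flags)
    df_t = pd.concat(targeted_frames, ignore_index=True)
    df_t["vaf"] = np.where(df_t["depth"] > 0, df_t["alt"] / df_t["depth"].clip(lower=1), np.nan)
    targeted = VariantTable(df_t, parent_flags=flags)

    # the category realized at the tissue level: bottleneck sampling can
    # shift the buccal L1 fractions away from the founder-level (a, b)
    ta, tb = samples["twin1_buccal"].l1_fraction, samples["twin2_buccal"].l1_fraction
    if ta < tb:
        ta, tb = tb, ta
    truth = {
        "family": family, "membrane": membrane, "zygosity": "MZ",
        "category": category, "mode": part.mode,
        "tissue_category": classify_category(ta, tb),
        "split_generation": part.split_generation,
        "true_a": part.true_a, "true_b": part.true_b,
        "buccal_a": samples["twin1_buccal"].l1_fraction,
        "buccal_b": samples["twin2_buccal"].l1_fraction,
        "blood_twin1_fraction": blood_f1,
        "variant_class": {
            vid: ("inherited" if vid in set(inh["variant"]) else catalog.loc[vid, "origin_class"])
            for vid in all_variants
        },
        "n_progenitors": {
            "buccal": config.buccal_progenitors, "cord_blood": config.blood_progenitors,
        },
    }
    return table, targeted, meta_rows, truth


def _simulate_dz_family(
    family: str, config: CohortConfig, rng: np.random.Generator
) -> tuple[VariantTable, list[dict], dict]:
    p = config.params
    samples: dict[str, TissueSample] = {}
    classes: dict[str, str] = {}
    for twin in ("twin1", "twin2"):
        tree, catalog = simulate_lineage(p, rng=rng)
        part = apply_twinning(tree, "full", config.full_split, allocation=0.5, rng=rng)
        # a dizygotic individual is the whole embryo: union of both "twins"
        whole = TwinPartition(
            {"self": tree.cells_at(config.full_split)}, "full", config.full_split,
            2, 1.0, 1.0, tree.n_generations,
        )
        samples[twin] = sample_tissue(
            tree, catalog, whole, "self", "buccal", config.buccal_progenitors, rng
        )
        samples[twin].individual = twin
        samples[twin].sample_id = f"{twin}_buccal"
        for vid in samples[twin].cell_fraction.index:
            classes[vid] = catalog.loc[vid, "origin_class"]
    inh = _inherited_block(config, rng, set())
    union = sorted(set(samples["twin1"].cell_fraction.index) | set(samples["twin2"].cell_fraction.index))
    count_frames, targeted_frames, meta_rows = [], [], []
    for twin in ("twin1", "twin2"):
        frac = samples[twin].cell_fraction.reindex(union, fill_value=0.0)
        frac = pd.concat([frac, pd.Series(1.0, index=inh["variant"])])
        reads = sequence_counts(frac, p.wgs_depth, p, rng)
        sid = f"{family}_{twin}_buccal"
        count_frames.append(_count_block(family, sid, reads))
        targeted_frames.append(
            _count_block(family, sid, sequence_counts(frac, p.targeted_depth, p, rng))
        )
        meta_rows.append(
            {
                "sample": sid, "family": family, "individual": f"{family}_{twin}",
                "tissue": "buccal", "zygosity": "DZ", "membrane": "DCDA",
            }
        )
    for parent in ("mother", "father"):
        frac_child = pd.Series(0.0, index=pd.Index(union))
        own = pd.Series(
            np.where(inh["parent"].to_numpy() == parent, 1.0, 0.0), index=inh["variant"]
        )
        reads = sequence_counts(pd.concat([frac_child, own]), p.parental_depth, p, rng)
        sid = f"{family}_{parent}"
        count_frames.append(_count_block(family, sid, reads))
        meta_rows.append(
            {
                "sample": sid, "family": family, "individual": sid,
                "tissue": "pbmc", "zygosity": "parent", "membrane": "DCDA",
            }
        )
    all_variants = list(union) + list(inh["variant"])
    flags = pd.DataFrame(False, index=pd.Index(all_variants), columns=["mother", "father"])
    for _, row in inh.iterrows():
        flags.loc[row["variant"], row["parent"]] = True
    df = pd.concat(count_frames, ignore_index=True)
    df["vaf"] = np.where(df["depth"] > 0, df["alt"] / df["depth"].clip(lower=1), np.nan)
    table = VariantTable(df, parent_flags=flags)
    df_t = pd.concat(targeted_frames, ignore_index=True)
    df_t["vaf"] = np.where(df_t["depth"] > 0, df_t["alt"] / df_t["depth"].clip(lower=1), np.nan)
    targeted = VariantTable(df_t, parent_flags=flags)
    truth = {
        "family": family, "membrane": "DCDA", "zygosity": "DZ", "category": "dizygotic",
        "variant_class": {
            vid: ("inherited" if vid in set(inh["variant"]) else classes[vid])
            for vid in all_variants
        },
    }
    return table, targeted, meta_rows, truth


def _simulate_triplet_family(
    family: str, config: CohortConfig, rng: np.random.Generator
) -> tuple[VariantTable, list[dict], dict]:
    p = config.params
    tree, catalog = simulate_lineage(p, rng=rng)
    part, topology = apply_triplet_twinning(tree, 4, 6, rng=rng)
    samples = {}
    for trip in ("triplet1", "triplet2", "triplet3"):
        samples[trip] = sample_tissue(
            tree, catalog, part, trip, "buccal", config.buccal_progenitors, rng
        )
    inh = _inherited_block(config, rng, set())
    union = sorted(set().union(*(set(s.cell_fraction.index) for s in samples.values())))
    count_frames, targeted_frames, meta_rows = [], [], []
    for trip, sample in samples.items():
        frac = sample.cell_fraction.reindex(union, fill_value=0.0)
        frac = pd.concat([frac, pd.Series(1.0, index=inh["variant"])])
        reads = sequence_counts(frac, p.wgs_depth, p, rng)
        sid = f"{family}_{trip}_buccal"
        count_frames.append(_count_block(family, sid, reads))
        targeted_frames.append(
            _count_block(family, sid, sequence_counts(frac, p.targeted_depth, p, rng))
        )
        meta_rows.append(
            {
                "sample": sid, "family": family, "individual": f"{family}_{trip}",
                "tissue": "buccal", "zygosity": "MZ", "membrane": "DCTA",
            }
        )
    for parent in ("mother", "father"):
        frac_child = pd.Series(0.0, index=pd.Index(union))
        own = pd.Series(
            np.where(inh["parent"].to_numpy() == parent, 1.0, 0.0), index=inh["variant"]
        )
        reads = sequence_counts(pd.concat([frac_child, own]), p.parental_depth, p, rng)
        sid = f"{family}_{parent}"
        count_frames.append(_count_block(family, sid, reads))
        meta_rows.append(
            {
                "sample": sid, "family": family, "individual": sid,
                "tissue": "pbmc", "zygosity": "parent", "membrane": "DCTA",
            }
        )
    all_variants = list(union) + list(inh["variant"])
    flags = pd.DataFrame(False, index=pd.Index(all_variants), columns=["mother", "father"])
    for _, row in inh.iterrows():
        flags.loc[row["variant"], row["parent"]] = True
    df = pd.concat(count_frames, ignore_index=True)
    df["vaf"] = np.where(df["depth"] > 0, df["alt"] / df["depth"].clip(lower=1), np.nan)
    table = VariantTable(df, parent_flags=flags)
    df_t = pd.concat(targeted_frames, ignore_index=True)
    df_t["vaf"] = np.where(df_t["depth"] > 0, df_t["alt"] / df_t["depth"].clip(lower=1), np.nan)
    targeted = VariantTable(df_t, parent_flags=flags)
    truth = {
        "family": family, "membrane": "DCTA", "zygosity": "MZ", "category": "triplet",
        "topology": topology,
        "variant_class": {
            vid: ("inherited" if vid in set(inh["variant"]) else catalog.loc[vid, "origin_class"])
            for vid in all_variants
        },
    }
    return table, targeted, meta_rows, truth


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortBundle:
    """Simulate the full twin cohort with per-family variant tables and truth.

    Default composition: 8 MCMA + 7 MCDA + 7 DCDA monozygotic pairs, one
    DCTA monozygotic triplet, and 6 dizygotic control pairs, each with trio
    (twins + parents) sequencing.
    """
    config = config or CohortConfig()
    tables: dict[str, VariantTable] = {}
    targeted: dict[str, VariantTable] = {}
    meta_rows: list[dict] = []
    truth: dict = {"seed": seed, "families": {}}
    for i, (family, membrane, category) in enumerate(_family_categories(config)):
        rng = np.random.default_rng([seed % (2**31), i])
        if category == "dizygotic":
            table, table_t, rows, fam_truth = _simulate_dz_family(family, config, rng)
        elif category == "triplet":
            table, table_t, rows, fam_truth = _simulate_triplet_family(family, config, rng)
        else:
            table, table_t, rows, fam_truth = _simulate_mz_family(
                family, membrane, category, config, rng
            )
        tables[family] = table
        targeted[family] = table_t
        meta_rows.extend(rows)
        truth["families"][family] = fam_truth
    metadata = pd.DataFrame(meta_rows)
    return CohortBundle(tables, targeted, metadata, truth)


def write_cohort(bundle: CohortBundle, outdir, formats=("tsv", "vcf")) -> None:
    """Write per-family variant tables, sample metadata, and the truth record."""
    from .variant_io import write_variant_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for family, table in bundle.tables.items():
        if "tsv" in formats:
            write_variant_table(table, out / f"{family}.tsv", "tsv")
            write_variant_table(bundle.targeted[family], out / f"{family}_targeted.tsv", "tsv")
        if "vcf" in formats:
            write_variant_table(table, out / f"{family}.vcf", "vcf")
            write_variant_table(bundle.targeted[family], out / f"{family}_targeted.vcf", "vcf")
    bundle.metadata.to_csv(out / "samples.tsv", sep="\t", index=False)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not serializable: {type(o)}")

    with open(out / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1, default=default)
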
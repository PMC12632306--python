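"""Dropout-aware reconstruction of early-lineage clades from single cells.

Single-cell genotypes produced by whole-genome amplification (MDA) suffer
two characteristic errors: locus dropout (the site yields no informative
reads at all, probability ``lambda``) and allelic dropout (a heterozygous
site loses its variant allele and reads as homozygous reference,
probability ``alpha``).  The observation model per cell x site is

    P(missing | anything)   = lambda
    P(alt     | true alt)   = (1 - lambda) (1 - alpha)
    P(ref     | true alt)   = (1 - lambda) alpha
    P(alt     | true ref)   = (1 - lambda) fp
    P(ref     | true ref)   = (1 - lambda) (1 - fp)

Reconstruction is greedy and top-down: the two earliest clades (L1 / L2)
are seeded with the anchor and counter-anchor marker EEMs from the bulk fit
(or, absent a fit, with the two most prevalent mutually exclusive variant
groups), each cell is assigned to the clade maximizing its summed
log-observation-likelihood, and the procedure recurses within clades on the
remaining variants.  Two markers count as mutually exclusive when their
observed co-occurrence does not exceed the 99th percentile expected from
the false-positive rate alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta, binom

REF, ALT, MISSING = 0, 1, -1
_STATE_STR = {REF: "0", ALT: "1", MISSING: "NA"}


@dataclass
class ScParams:
    """Single-cell amplification error rates.

    ado_rate (alpha): allelic dropout — a true heterozygous site observed
    as reference.  locus_dropout (lambda): the site is entirely missing.
    fp_rate: a true reference site observed as alternate.
    """

    ado_rate: float = 0.23
    locus_dropout: float = 0.46
    fp_rate: float = 0.01
    n_cells: int = 80

    def __post_init__(self):
        for name in ("ado_rate", "locus_dropout", "fp_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")


@dataclass
class ScGenotypeMatrix:
    """Cells x variants tri-state genotype matrix (0 = ref, 1 = alt, -1 = missing)."""

    data: pd.DataFrame  # int8 codes
    cell_twin: pd.Series | None = None  # per-cell twin-of-origin label
    params: ScParams = field(default_factory=ScParams)

    def __post_init__(self):
        vals = set(np.unique(self.data.to_numpy()))
        if not vals <= {REF, ALT, MISSING}:
            raise ValueError(f"genotype states must be 0/1/-1, got {vals}")

    @property
    def cells(self):
        return list(self.data.index)

    @property
    def variants(self):
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        out = self.data.map(lambda v: _STATE_STR[int(v)])
        out.to_csv(path, sep="\t", index_label="cell")

    @classmethod
    def from_tsv(cls, path, params: ScParams | None = None) -> "ScGenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="cell", dtype=str, keep_default_na=False)
        rev = {"0": REF, "1": ALT, "NA": MISSING}
        codes = df.map(lambda s: rev[s]).astype(np.int8)
        return cls(codes, params=params or ScParams())


def observation_likelihood(observed: int, true_alt: bool, sc: ScParams) -> float:
    """Probability of an observed state given the true genotype."""
    lam, alpha, fp = sc.locus_dropout, sc.ado_rate, sc.fp_rate
    if observed == MISSING:
        return lam
    if true_alt:
        return (1 - lam) * (1 - alpha) if observed == ALT else (1 - lam) * alpha
    return (1 - lam) * fp if observed == ALT else (1 - lam) * (1 - fp)


def _log_obs(observed: np.ndarray, true_alt: bool, sc: ScParams) -> np.ndarray:
    lam, alpha, fp = sc.locus_dropout, sc.ado_rate, sc.fp_rate
    p_alt = (1 - lam) * (1 - alpha) if true_alt else (1 - lam) * fp
    p_ref = (1 - lam) * alpha if true_alt else (1 - lam) * (1 - fp)
    # a hard floor instead of -inf keeps score gaps finite (and NaN-free)
    # for impossible observations such as a false positive at fp_rate = 0
    out = np.full(observed.shape, np.log(max(lam, 1e-300)))
    out[observed == ALT] = np.log(max(p_alt, 1e-300))
    out[observed == REF] = np.log(max(p_ref, 1e-300))
    return out


def mutually_exclusive(
    matrix: pd.DataFrame, v: str, w: str, sc: ScParams, q: float = 0.99
) -> bool:
    """Do markers v and w co-occur no more than expected from false positives?

    Under the null that no cell truly carries both, a cell observed alt at
    one marker reads alt at the other (given it is not missing) with
    probability ``fp_rate``; the observed co-occurrence count is compared
    with the ``q`` quantile of the corresponding binomial.
    """
    a = matrix[v].to_numpy()
    b = matrix[w].to_numpy()
    co = int(((a == ALT) & (b == ALT)).sum())
    n_trials = int(((a == ALT) & (b != MISSING)).sum() + ((b == ALT) & (a != MISSING)).sum())
    if n_trials == 0:
        return True
    thresh = int(binom.ppf(q, n_trials, sc.fp_rate))
    return co <= thresh


@dataclass
class ScPhylogeny:
    newick: str
    assignments: pd.Series  # cell -> clade path, e.g. "L1" or "L1/L1-1"
    scores: pd.Series  # log-likelihood gap supporting the top-level assignment
    clade_markers: dict  # clade path -> list of marker variants
    status: str = "ok"


def _alt_counts(matrix: pd.DataFrame) -> pd.Series:
    return (matrix == ALT).sum(axis=0)


def _seed_marker_groups(matrix: pd.DataFrame, sc: ScParams) -> tuple[list, list] | None:
    """Find the two most prevalent mutually exclusive variant groups.

    Variants are joined into a group when they co-occur above chance
    (i.e. are NOT mutually exclusive); groups are connected components of
    that co-occurrence graph, ranked by total alt-cell support.
    """
    variants = [v for v in matrix.columns if (matrix[v] == ALT).any()]
    if len(variants) < 2:
        return None
    parent = {v: v for v in variants}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, v in enumerate(variants):
        for w in variants[i + 1 :]:
            if not mutually_exclusive(matrix, v, w, sc):
                parent[find(v)] = find(w)
    groups: dict[str, list] = {}
    for v in variants:
        groups.setdefault(find(v), []).append(v)
    alt_n = _alt_counts(matrix)
    ranked = sorted(groups.values(), key=lambda g: (-int(alt_n[g].sum()), g[0]))
    # the two top groups must be mutually exclusive with each other
    for j in range(1, len(ranked)):
        g2 = ranked[j]
        if all(mutually_exclusive(matrix, v, w, sc) for v in ranked[0] for w in g2):
            return ranked[0], g2
    return None


def _assign_cells(
    matrix: pd.DataFrame, markers_a: list, markers_b: list, sc: ScParams
) -> tuple[pd.Series, pd.Series]:
    """Assign each cell to clade A or B by summed observation log-likelihood."""
    cols = list(dict.fromkeys(list(markers_a) + list(markers_b)))
    obs = matrix[cols].to_numpy()
    col_idx = {c: i for i, c in enumerate(cols)}

    def clade_ll(own: list, other: list) -> np.ndarray:
        ll = np.zeros(len(matrix))
        for v in own:
            ll += _log_obs(obs[:, col_idx[v]], True, sc)
        for v in other:
            ll += _log_obs(obs[:, col_idx[v]], False, sc)
        return ll

    ll_a = clade_ll(markers_a, markers_b)
    ll_b = clade_ll(markers_b, markers_a)
    gap = ll_a - ll_b
    label = np.asarray(np.where(gap > 0, "A", "B"), dtype=object)
    # cells with a score gap under one log-unit are not forced; an exact
    # tie with asymmetric marker coverage is broken toward the clade with
    # more observed (non-missing) marker sites
    amb = np.abs(gap) < 1.0
    obs_a = (matrix[markers_a] != MISSING).sum(axis=1).to_numpy()
    obs_b = (matrix[markers_b] != MISSING).sum(axis=1).to_numpy()
    label[amb] = "ambiguous"
    tie = amb & (gap == 0)
    label[tie & (obs_a > obs_b)] = "A"
    label[tie & (obs_b > obs_a)] = "B"
    return pd.Series(label, index=matrix.index), pd.Series(gap, index=matrix.index)


def reconstruct_sc_phylogeny(
    matrix: ScGenotypeMatrix,
    markers: dict | None = None,
    seed: int = 0,
    min_clade_cells: int = 4,
    max_depth: int = 3,
) -> ScPhylogeny:
    """Greedy top-down clade reconstruction of a single-cell genotype matrix.

    ``markers`` may supply the bulk anchor fit's marker sets as
    ``{"L1": [...], "L2": [...]}``; otherwise the two most prevalent
    mutually exclusive variant groups seed the top split.  Cells whose
    top-level log-likelihood gap is below one log-unit are labelled
    ``ambiguous`` rather than forced.
    """
    sc = matrix.params
    df = matrix.data
    if not (df != MISSING).to_numpy().any():
        return ScPhylogeny("", pd.Series(dtype=object), pd.Series(dtype=float), {}, "failed")

    if markers is not None:
        m1 = [v for v in markers.get("L1", []) if v in df.columns]
        m2 = [v for v in markers.get("L2", []) if v in df.columns]
        # bulk-derived marker sets are re-validated against the cells: a
        # putative counter-anchor variant that co-occurs with the anchor
        # markers belongs downstream of L1, not to L2 (and vice versa), so
        # it is dropped here and placed by the within-clade recursion
        if m1 and m2:
            m2 = [w for w in m2 if all(mutually_exclusive(df, v, w, sc) for v in m1)]
            m1 = [v for v in m1 if all(mutually_exclusive(df, v, w, sc) for w in m2)]
        if not m1 or not m2:
            markers = None
    if markers is None:
        seeded = _seed_marker_groups(df, sc)
        if seeded is None:
            return ScPhylogeny(
                "", pd.Series(dtype=object), pd.Series(dtype=float), {}, "failed"
            )
        m1, m2 = seeded

    labels, gaps = _assign_cells(df, m1, m2, sc)
    clade_markers = {"L1": list(m1), "L2": list(m2)}
    paths = labels.map({"A": "L1", "B": "L2", "ambiguous": "ambiguous"})
    used = set(m1) | set(m2)

    children: dict[str, list[str]] = {"L1": [], "L2": []}

    def recurse(path: str, cells: pd.Index, depth: int) -> None:
        if depth >= max_depth or len(cells) < 2 * min_clade_cells:
            return
        remaining = [v for v in df.columns if v not in used]
        sub = df.loc[cells, remaining]
        seeded = _seed_marker_groups(sub, sc)
        if seeded is None:
            return
        ma, mb = seeded
        if (sub[ma] == ALT).any().sum() == 0 or (sub[mb] == ALT).any().sum() == 0:
            return
        sub_labels, _ = _assign_cells(sub, ma, mb, sc)
        n_a = int((sub_labels == "A").sum())
        n_b = int((sub_labels == "B").sum())
        if n_a < min_clade_cells or n_b < min_clade_cells:
            return
        pa, pb = f"{path}/{path.split('/')[-1]}-1", f"{path}/{path.split('/')[-1]}-2"
        used.update(ma)
        used.update(mb)
        clade_markers[pa] = list(ma)
        clade_markers[pb] = list(mb)
        children.setdefault(path, []).extend([pa, pb])
        children.setdefault(pa, [])
        children.setdefault(pb, [])
        for cell in cells:
            lab = sub_labels[cell]
            if lab == "A":
                paths.loc[cell] = pa
            elif lab == "B":
                paths.loc[cell] = pb
        recurse(pa, cells[(sub_labels == "A").to_numpy()], depth + 1)
        recurse(pb, cells[(sub_labels == "B").to_numpy()], depth + 1)

    recurse("L1", df.index[(labels == "A").to_numpy()], 1)
    recurse("L2", df.index[(labels == "B").to_numpy()], 1)

    def to_newick(node: str) -> str:
        kids = children.get(node, [])
        name = node.split("/")[-1]
        if not kids:
            return name
        return "(" + ",".join(to_newick(k) for k in kids) + ")" + name

    newick = f"({to_newick('L1')},{to_newick('L2')})zygote;"
    return ScPhylogeny(newick, paths, gaps.abs(), clade_markers, "ok")


def lineage_contribution(
    phylogeny: ScPhylogeny, cell_twin: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-twin fraction of assigned cells in the L1 clade, with binomial CIs.

    Clopper-Pearson intervals; cells labelled ``ambiguous`` are excluded.
    Twins with zero assigned cells get NaN fractions.
    """
    top = phylogeny.assignments.map(
        lambda p: p.split("/")[0] if isinstance(p, str) else p
    )
    rows = []
    for twin in pd.unique(cell_twin):
        cells = cell_twin.index[cell_twin == twin]
        assigned = top.loc[top.index.intersection(cells)]
        assigned = assigned[assigned != "ambiguous"]
        n = len(assigned)
        k = int((assigned == "L1").sum())
        if n == 0:
            rows.append((twin, np.nan, np.nan, np.nan, 0))
            continue
        lo = beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
        hi = beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
        rows.append((twin, k / n, float(lo), float(hi), n))
    return pd.DataFrame(
        rows, columns=["twin", "l1_fraction", "ci_low", "ci_high", "n_cells"]
    ).set_index("twin")
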
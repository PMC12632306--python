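"""Two-lineage clonal deconvolution of twin pairs from EEM VAFs.

The cell-genealogy model: the somatic tissues of a monozygotic twin pair are
drawn from the two earliest informative ancestral cells, L1 (dominant) and
L2, with L1 contributing fractions ``a`` and ``b`` to Twin 1 and Twin 2
(Twin 1 is defined so that a >= b).  Heterozygous mutations carried by L1
("anchor cluster") then sit at VAFs (a/2, b/2) in twin-vs-twin VAF space,
and mutations carried by L2 ("counter-anchor cluster") at ((1-a)/2,
(1-b)/2) — the point reflection of the anchor through (0.25, 0.25).  Because
L1 and L2 jointly account for all somatic cells, 2*v_anchor + 2*v_counter =
1 in each twin, and anchor VAFs satisfy the sum rule v1 + v2 >= 0.5.

Estimation clusters the observed EEM VAF pairs, selects the anchor cluster
by the sum rule, pairs it with its point-symmetric counter-anchor, and reads
(a, b) off the cluster centroids.  The fitted (a, b) classifies the pair as
para-identical (a=1, b=0), sub-identical (a=1, 0<b<1), or full-identical
(a ~= b < 1), with an explicit fourth label ``discordant`` for fits that
match none of the three patterns: the three categories do not tile
(a, b)-space, and forcing a label would hide a poor fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

CENTER = (0.25, 0.25)  # reflection point of the anchor/counter-anchor pair


class AnchorFitError(RuntimeError):
    """No usable cluster structure in the EEM VAFs."""


@dataclass
class ModelConfig:
    """Tunable knobs of the anchor-model fit.

    link_radius:
        Agglomerative merge radius (average linkage) in 2-D VAF space.
    symmetry_tol:
        Maximum distance between the counter-anchor centroid and the point
        reflection of the anchor centroid through (0.25, 0.25).
    anchor_sum_min:
        The anchor sum rule: summed centroid VAF across both twins must be
        at least this (0.5 under the model, since a + b >= 1 for L1).
    epsilon:
        Tolerance for the category boundaries "a = 1", "b = 0", "a ~= b".
    min_cluster_size:
        Smallest cluster considered; single-EEM clusters are informative at
        targeted depth and are accepted by default.
    founder_rate:
        Expected mutations per cell per division, for converting unique
        clonal mutation counts into division counts.
    """

    link_radius: float = 0.05
    symmetry_tol: float = 0.10
    anchor_sum_min: float = 0.5
    epsilon: float = 0.10
    min_cluster_size: int = 1
    founder_rate: float = 1.2

    def __post_init__(self):
        for name in ("link_radius", "symmetry_tol", "anchor_sum_min", "epsilon"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.founder_rate <= 0:
            raise ValueError("founder_rate must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class Cluster:
    members: list  # variant ids (or integer indices)
    centroid: tuple[float, float]
    twin1_var: float = 0.0  # spread of Twin-1 VAFs, used only for tie-breaks

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def centroid_sum(self) -> float:
        return float(self.centroid[0] + self.centroid[1])


@dataclass
class AnchorFit:
    anchor: Cluster | None
    counter_anchor: Cluster | None
    a: float
    b: float
    twin_order: tuple[str, str]  # (Twin 1, Twin 2) after ordering so a >= b
    category: str
    epsilon: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _single_linkage_clusters(points: np.ndarray, ids, config: ModelConfig) -> list[Cluster]:
    n = len(points)
    if n == 0:
        raise AnchorFitError("no EEM VAF pairs to cluster")
    if n == 1:
        labels = np.array([1])
    else:
        # average linkage: single linkage chains adjacent subclonal EEMs
        # into the anchor cluster when private VAFs form a continuum
        z = linkage(pdist(points), method="average")
        labels = fcluster(z, t=config.link_radius, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        centroid = points[idx].mean(axis=0)
        clusters.append(
            Cluster(
                [ids[i] for i in idx],
                (float(centroid[0]), float(centroid[1])),
                float(np.var(points[idx, 0])),
            )
        )
    return clusters


def detect_anchor_clusters(
    vafs, config: ModelConfig | None = None, ids=None
) -> tuple[Cluster | None, Cluster | None]:
    """Find the anchor and counter-anchor EEM clusters in (twin1, twin2) VAF space.

    ``vafs`` is an (n, 2) array-like of per-EEM VAF pairs.  Returns
    ``(anchor, counter_anchor)``; the anchor is ``None`` when no cluster
    passes the sum rule, in which case the most plausible counter-anchor is
    still returned (largest summed-VAF cluster on the sub-diagonal side,
    whose reflection would be a valid anchor).
    """
    config = config or ModelConfig()
    points = np.atleast_2d(np.asarray(vafs, dtype=float))
    if ids is None:
        ids = list(range(len(points)))
    clusters = _single_linkage_clusters(points, ids, config)
    eligible = [c for c in clusters if c.size >= config.min_cluster_size]
    if not eligible:
        raise AnchorFitError("no cluster reaches min_cluster_size")

    anchored = [c for c in eligible if c.centroid_sum >= config.anchor_sum_min]
    anchor = None
    if anchored:
        # max summed centroid VAF; ties -> larger cluster, then tighter Twin-1 spread
        anchor = max(anchored, key=lambda c: (round(c.centroid_sum, 12), c.size, -c.twin1_var))

    if anchor is not None:
        target = (0.5 - anchor.centroid[0], 0.5 - anchor.centroid[1])
        others = [c for c in eligible if c is not anchor]
        counter = None
        if others:
            dists = [np.hypot(c.centroid[0] - target[0], c.centroid[1] - target[1]) for c in others]
            best = int(np.argmin(dists))
            if dists[best] <= config.symmetry_tol:
                counter = others[best]
        return anchor, counter

    # anchor absent: the counter-anchor is the dominant cluster below the
    # sum rule whose reflection through (0.25, 0.25) would itself qualify
    # as an anchor (reflected sum = 1 - centroid_sum >= anchor_sum_min)
    candidates = [c for c in eligible if 1 - c.centroid_sum >= config.anchor_sum_min]
    if not candidates:
        raise AnchorFitError("no counter-anchor candidate found")
    counter = max(candidates, key=lambda c: (round(c.centroid_sum, 12), c.size))
    return None, counter


def estimate_ab(
    anchor: Cluster | None,
    counter: Cluster | None,
    config: ModelConfig | None = None,
    twin_names: tuple[str, str] = ("twin1", "twin2"),
) -> tuple[float, float, tuple[str, str]]:
    """Estimate (a, b) from the anchor and/or counter-anchor centroids.

    The anchor centroid (v1, v2) gives (2 v1, 2 v2); the counter centroid
    (u1, u2) gives (1 - 2 u1, 1 - 2 u2).  When both clusters are present
    the two readings are combined by a weighted average with weights
    proportional to cluster size (the centroid variance scales as 1/size).
    Twin labels are swapped if needed so that a >= b.
    """
    config = config or ModelConfig()
    if anchor is None and counter is None:
        raise AnchorFitError("need at least one of anchor / counter-anchor")
    estimates, weights = [], []
    if anchor is not None:
        estimates.append((2 * anchor.centroid[0], 2 * anchor.centroid[1]))
        weights.append(anchor.size)
    if counter is not None:
        estimates.append((1 - 2 * counter.centroid[0], 1 - 2 * counter.centroid[1]))
        weights.append(counter.size)
    est = np.average(np.asarray(estimates), axis=0, weights=np.asarray(weights, dtype=float))
    a, b = float(np.clip(est[0], 0, 1)), float(np.clip(est[1], 0, 1))
    order = twin_names
    if a < b:
        a, b = b, a
        order = (twin_names[1], twin_names[0])
    return a, b, order


def classify_category(a: float, b: float, epsilon: float = 0.10) -> str:
    """Map contributions (a, b), a >= b, to a clonal category.

    para: a = 1, b = 0; sub: a = 1, 0 < b < 1; full: a ~= b < 1 — each up
    to the tolerance ``epsilon``; anything else is ``discordant``.
    """
    if not (0 <= b <= a <= 1):
        raise ValueError("require 0 <= b <= a <= 1")
    if a >= 1 - epsilon and b <= epsilon:
        return "para"
    if a >= 1 - epsilon and epsilon < b < 1 - epsilon:
        return "sub"
    if a < 1 - epsilon and abs(a - b) <= 2 * epsilon:
        return "full"
    return "discordant"


def _merge_clusters(ci: Cluster, cj: Cluster) -> Cluster:
    """Composite cluster whose centroid is the *sum* of two daughters' centroids.

    When the L1 ancestor itself carries no detectable EEM, its two daughter
    lineages' clusters add up to the anchor position (carrier fractions are
    additive over disjoint sublineages).
    """
    return Cluster(
        list(ci.members) + list(cj.members),
        (ci.centroid[0] + cj.centroid[0], ci.centroid[1] + cj.centroid[1]),
    )


def _pair_score(a: Cluster, c: Cluster) -> float:
    """Deviation from the model identity anchor + counter = (0.5, 0.5)."""
    return float(
        np.hypot(
            a.centroid[0] + c.centroid[0] - 0.5, a.centroid[1] + c.centroid[1] - 0.5
        )
    )


def fit_pair(
    vafs, config: ModelConfig | None = None, ids=None,
    twin_names: tuple[str, str] = ("twin1", "twin2"),
) -> AnchorFit:
    """Full anchor-model fit of one twin pair from its EEM VAF pairs.

    The fit searches anchor/counter-anchor cluster pairs for the best match
    to the model identity (their centroids sum to (0.5, 0.5)).  When no
    single cluster passes the anchor sum rule, two sub-threshold clusters
    may be combined as the daughters of an EEM-free L1 ancestor (flagged
    ``composite_anchor``).  When anchor and counter evidence cannot be
    paired symmetrically, their two readings of (a, b) — biased in opposite
    directions by missing early witnesses — are averaged and flagged
    ``asymmetric_pair``.
    """
    config = config or ModelConfig()
    points = np.atleast_2d(np.asarray(vafs, dtype=float))
    if ids is None:
        ids = list(range(len(points)))
    clusters = _single_linkage_clusters(points, ids, config)
    eligible = [c for c in clusters if c.size >= config.min_cluster_size]
    if not eligible:
        raise AnchorFitError("no cluster reaches min_cluster_size")
    # candidacy carries a noise margin: a para-identical anchor sits
    # exactly at the sum-rule boundary (a + b = 1), so read noise and
    # cluster merging would otherwise disqualify it half the time
    margin = config.symmetry_tol / 2
    cand_a = [c for c in eligible if c.centroid_sum >= config.anchor_sum_min - margin]
    cand_c = [c for c in eligible if c.centroid_sum <= 1 - config.anchor_sum_min + margin]

    flags: list[str] = []
    anchor = counter = None
    weighted = True

    # 1. best symmetric anchor/counter single-cluster pair under the
    # midpoint identity
    best = None
    for a_cl in cand_a:
        for c_cl in cand_c:
            if set(a_cl.members) & set(c_cl.members):
                continue
            s = _pair_score(a_cl, c_cl)
            if s <= config.symmetry_tol and (best is None or s < best[0]):
                best = (s, a_cl, c_cl)
    if best is not None:
        anchor, counter = best[1], best[2]
    elif not cand_a:
        # 2. composite anchor: when the L1 ancestor carries no detectable
        # EEM of its own, its two daughter lineages' clusters sum to the
        # missing anchor's position; a genuine composite matches the
        # identity to read-noise accuracy, so the threshold is tighter
        best = None
        for i in range(len(cand_c)):
            for j in range(i + 1, len(cand_c)):
                comp = _merge_clusters(cand_c[i], cand_c[j])
                if comp.centroid_sum < config.anchor_sum_min - margin:
                    continue
                for c_cl in cand_c:
                    if set(comp.members) & set(c_cl.members):
                        continue
                    s = _pair_score(comp, c_cl)
                    if s <= config.symmetry_tol / 2 and (best is None or s < best[0]):
                        best = (s, comp, c_cl)
        if best is not None:
            anchor, counter = best[1], best[2]
            flags.append("composite_anchor")
    if anchor is None and counter is None:
        # 3. unpaired evidence: strongest anchor candidate, then the
        # strongest counter candidate compatible with per-twin conservation
        # (L1 + L2 fractions cannot exceed the whole tissue: v_i + u_i <= 0.5)
        if cand_a:
            anchor = max(cand_a, key=lambda c: (round(c.centroid_sum, 12), c.size, -c.twin1_var))
        # a credible counter-anchor implies a + b = 2 - 2*(u1 + u2) well
        # below 2; clusters summing under 0.1 are deep-sublineage scatter
        compatible = [
            c for c in cand_c
            if c.centroid_sum >= 0.1
            and (
                anchor is None
                or (
                    c.centroid[0] + anchor.centroid[0] <= 0.5 + config.symmetry_tol
                    and c.centroid[1] + anchor.centroid[1] <= 0.5 + config.symmetry_tol
                )
            )
        ]
        if anchor is not None:
            # a cluster passing the sum rule is a near-complete L1 witness;
            # a counter candidate that cannot pair with it symmetrically is
            # an ambiguous deep sublineage and is excluded from the estimate
            flags.append("counter_anchor_absent")
            if compatible:
                flags.append("counter_inconsistent")
        elif compatible:
            # larger clusters are likelier to be a true ancestral lineage's
            # EEM set than a stray deep sublineage
            counter = max(compatible, key=lambda c: (round(c.centroid_sum, 12), c.size))
            flags.append("anchor_absent")
        else:
            flags.append("anchor_absent")

    if anchor is None and counter is None:
        raise AnchorFitError("no anchor or counter-anchor candidate found")
    if weighted:
        a, b, order = estimate_ab(anchor, counter, config, twin_names=twin_names)
    else:
        est_a = np.array([2 * anchor.centroid[0], 2 * anchor.centroid[1]])
        est_c = np.array([1 - 2 * counter.centroid[0], 1 - 2 * counter.centroid[1]])
        est = np.clip((est_a + est_c) / 2.0, 0, 1)
        a, b = float(est[0]), float(est[1])
        order = twin_names
        if a < b:
            a, b = b, a
            order = (twin_names[1], twin_names[0])
    if order != twin_names:
        # re-express cluster centroids in Twin-1-first coordinates
        if anchor is not None:
            anchor = Cluster(anchor.members, (anchor.centroid[1], anchor.centroid[0]))
        if counter is not None:
            counter = Cluster(counter.members, (counter.centroid[1], counter.centroid[0]))
    category = classify_category(a, b, config.epsilon)
    if category == "discordant":
        flags.append("discordant_fit")
    return AnchorFit(anchor, counter, a, b, order, category, config.epsilon, flags)


# -- summaries over EEM calls --------------------------------------------


def genetic_distance(detected: pd.DataFrame) -> int:
    """Number of EEM events detected in exactly one co-twin.

    ``detected`` is a boolean DataFrame (EEM x 2 twins) of detection flags.
    """
    det = np.asarray(detected, dtype=bool)
    if det.ndim != 2 or det.shape[1] != 2:
        raise ValueError("expect an EEM x 2 detection matrix")
    return int((det.sum(axis=1) == 1).sum())


def divisions_between_founders(
    n_unique_clonal: int, founder_rate: float = 1.2, mode: str = "round"
) -> int:
    """Convert a unique clonal mutation count into cell divisions.

    With mutations accruing at ``founder_rate`` per cell per division,
    ``n`` unique clonal mutations correspond to n / rate divisions —
    rounded to the nearest integer, or floored for "at least" statements
    (``mode="floor"``).
    """
    if n_unique_clonal < 0:
        raise ValueError("mutation count must be non-negative")
    if founder_rate <= 0:
        raise ValueError("founder_rate must be positive")
    x = n_unique_clonal / founder_rate
    if mode == "round":
        return int(np.floor(x + 0.5))
    if mode == "floor":
        return int(np.floor(x))
    raise ValueError(f"unknown mode: {mode}")


# -- multi-tissue refinement and triplet topology ------------------------


@dataclass
class RefinedLineage:
    labels: pd.Series  # EEM id -> cluster name
    clusters: pd.DataFrame  # per cluster: mean VAF per sample + n members
    newick: str


def multisample_refine(
    vaf_matrix: pd.DataFrame,
    cut_height: float = 0.3,
    detect_vaf: float = 0.03,
) -> RefinedLineage:
    """Refine EEM clusters using VAF profiles across three or more samples.

    EEMs are clustered on their VAF profile across all samples (correlation
    distance, average linkage, tree cut at ``cut_height``), and the clusters
    are ordered into a nesting-consistent lineage by containment of their
    detection patterns (a cluster detected in a superset of samples is
    ancestral).  Returns per-EEM cluster labels and a Newick tree of
    clusters.
    """
    if vaf_matrix.shape[1] < 3:
        raise ValueError(
            "multisample refinement needs >= 3 samples; use the two-sample anchor fit"
        )
    x = vaf_matrix.to_numpy(dtype=float)
    x = np.nan_to_num(x, nan=0.0)
    n = len(x)
    if n == 0:
        raise ValueError("empty VAF matrix")
    if n == 1:
        labels = np.array([1])
    else:
        # correlation distance, with flat (zero-variance) profiles handled
        # explicitly: two flat profiles are identical (distance 0), and a
        # flat profile is uninformative about any varying one (distance 1)
        rows = x - x.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(rows, axis=1)
        flat = norm == 0
        unit = np.zeros_like(rows)
        unit[~flat] = rows[~flat] / norm[~flat, None]
        dmat = 1.0 - unit @ unit.T
        dmat[np.ix_(flat, flat)] = 0.0
        dmat[np.ix_(flat, ~flat)] = 1.0
        dmat[np.ix_(~flat, flat)] = 1.0
        np.fill_diagonal(dmat, 0.0)
        dmat = np.clip((dmat + dmat.T) / 2, 0, 2)
        from scipy.spatial.distance import squareform

        z = linkage(squareform(dmat, checks=False), method="average")
        labels = fcluster(z, t=cut_height, criterion="distance")

    uniq_labels = list(np.unique(labels))
    member_idx = [np.where(labels == lab)[0] for lab in uniq_labels]
    mean_vafs = np.vstack([x[idx].mean(axis=0) for idx in member_idx])
    detect = mean_vafs >= detect_vaf
    # name clusters by breadth of detection, then total VAF (C1 = broadest)
    breadth = detect.sum(axis=1)
    total = mean_vafs.sum(axis=1)
    order = sorted(range(len(uniq_labels)), key=lambda i: (-breadth[i], -total[i]))
    cname = {uniq_labels[i]: f"C{rank + 1}" for rank, i in enumerate(order)}
    labels_named = pd.Series(
        [cname[lab] for lab in labels], index=vaf_matrix.index, name="cluster"
    )
    cluster_df = pd.DataFrame(mean_vafs, columns=vaf_matrix.columns)
    cluster_df["n_members"] = [len(idx) for idx in member_idx]
    cluster_df.index = [cname[lab] for lab in uniq_labels]
    cluster_df = cluster_df.loc[sorted(cluster_df.index, key=lambda s: int(s[1:]))]

    # containment-based nesting: parent = smallest strict superset pattern
    pats = {}
    for i, lab in enumerate(uniq_labels):
        pats[cname[lab]] = frozenset(np.where(detect[i])[0])
    children: dict[str | None, list[str]] = {None: []}
    parent_of = {}
    ordered = sorted(pats, key=lambda c: (-len(pats[c]), c))
    for c in ordered:
        best = None
        for p in ordered:
            if p == c:
                continue
            if pats[c] < pats[p] or (pats[c] == pats[p] and ordered.index(p) < ordered.index(c)):
                if best is None or len(pats[p]) < len(pats[best]):
                    best = p
        parent_of[c] = best
        children.setdefault(best, []).append(c)
        children.setdefault(c, [])

    def to_newick(node) -> str:
        kids = children.get(node, [])
        label = "" if node is None else node
        if not kids:
            return label
        inner = ",".join(to_newick(k) for k in kids)
        return f"({inner}){label}"

    roots = children[None]
    if len(roots) == 1:
        newick = to_newick(roots[0]) + ";"
    else:
        newick = "(" + ",".join(to_newick(r) for r in roots) + ")zygote;"
    return RefinedLineage(labels_named, cluster_df, newick)


@dataclass
class TripletTopology:
    newick: str
    status: str  # resolved | star | unresolvable
    join_order: list


def triplet_topology(pair_fits: dict, shared_counts: dict) -> TripletTopology:
    """Order three individuals into a founder tree from pairwise fits.

    The pair with the most shared clonal EEMs coalesces last (latest MRCA)
    and is joined first; in each sub-identical pair the pure (a = 1) member
    is the nested, later-founded individual, which fixes the nesting
    direction.  Mutually para-identical pairs carry no nesting signal and
    yield a star; contradictory nesting is flagged unresolvable.
    """
    pairs = list(shared_counts)
    individuals = sorted({i for p in pairs for i in p})
    if len(individuals) != 3 or len(pairs) != 3:
        raise ValueError("need exactly three individuals with three pairwise entries")
    cats = {p: pair_fits[p].category for p in pairs}
    if all(c == "para" for c in cats.values()):
        newick = "(" + ",".join(individuals) + ");"
        return TripletTopology(newick, "star", [])
    first = max(pairs, key=lambda p: shared_counts[p])
    outer = next(i for i in individuals if i not in first)
    # consistency: in each sub pair involving the outer individual, the
    # outer one must be the non-pure (enclosing) member
    for p in pairs:
        if p == first or cats[p] != "sub":
            continue
        fit = pair_fits[p]
        pure = fit.twin_order[0]  # Twin 1 (a = 1) is the nested member
        if outer in p and pure == outer:
            return TripletTopology("", "unresolvable", [])
    inner = sorted(first)
    newick = f"(({inner[0]},{inner[1]}),{outer});"
    return TripletTopology(newick, "resolved", [tuple(inner), outer])
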
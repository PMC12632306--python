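"""Maximum-likelihood estimation of cord-blood mixing between co-twins.

Monochorionic twins exchange hematopoietic cells through the shared
placenta, so each cord-blood sample is a mixture of the two twins'
hematopoietic lineages.  EEMs that are fully clonal in exactly one twin's
soma (buccal VAF near 0.5 in the source twin, absent in the co-twin) are
informative markers of lineage origin: a blood sample containing a fraction
``m`` of cells from the Twin-2 lineage shows a Twin-2-sourced marker at
expected VAF m/2 and a Twin-1-sourced marker at (1 - m)/2.  The mixing
fraction is estimated by maximizing the binomial read-count likelihood on a
grid with golden-section refinement, with a 95% profile-likelihood interval
(log-likelihood drop of 1.92).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import binom

PROFILE_DROP = 1.92  # chi-square(1) 95% / 2


@dataclass
class MixingEstimate:
    sample: str
    m: float | None  # fraction of cells from the Twin-2 lineage
    ci: tuple[float, float] | None
    loglik: float | None
    n_informative: int
    status: str  # ok | no_informative_eems

    @property
    def major_contributor(self) -> float | None:
        if self.m is None:
            return None
        return max(self.m, 1 - self.m)


def select_informative(
    buccal_vafs: pd.DataFrame,
    clonal_min_vaf: float = 0.4,
    absent_max_vaf: float = 0.02,
) -> pd.DataFrame:
    """EEMs clonal in exactly one twin's buccal tissue and absent in the other.

    ``buccal_vafs`` is an EEM x 2 DataFrame (columns: Twin 1 and Twin 2
    buccal VAFs).  Returns a DataFrame indexed by EEM id with a
    ``source_twin`` column (1 or 2).  An empty result is valid:
    full-identical pairs typically have no twin-unique clonal EEM.
    """
    if buccal_vafs.shape[1] != 2:
        raise ValueError("expect buccal VAFs for exactly two twins")
    v1 = buccal_vafs.iloc[:, 0].to_numpy(dtype=float)
    v2 = buccal_vafs.iloc[:, 1].to_numpy(dtype=float)
    src1 = (v1 >= clonal_min_vaf) & (np.nan_to_num(v2) <= absent_max_vaf)
    src2 = (v2 >= clonal_min_vaf) & (np.nan_to_num(v1) <= absent_max_vaf)
    out = pd.DataFrame(index=buccal_vafs.index[src1 | src2])
    out["source_twin"] = np.where(src1[src1 | src2], 1, 2)
    return out


def _loglik_grid(m_grid, alt, depth, source, err):
    """Binomial log-likelihood of mixing fractions, vectorized over the grid."""
    m = np.asarray(m_grid, dtype=float)[:, None]
    p = np.where(source[None, :] == 2, m / 2.0, (1.0 - m) / 2.0)
    p = np.clip(p, err, 0.5)
    return binom.logpmf(alt[None, :], depth[None, :], p).sum(axis=1)


def estimate_mixing(
    informative: pd.DataFrame,
    blood_counts: pd.DataFrame,
    seq_error: float = 0.001,
    grid_step: float = 1e-3,
) -> MixingEstimate:
    """ML estimate of one cord-blood sample's Twin-2 lineage fraction.

    ``informative`` comes from :func:`select_informative`; ``blood_counts``
    is indexed by EEM id with columns ``depth`` and ``alt`` for the sample
    (its name is taken from ``blood_counts.attrs.get('sample')`` or
    defaults to 'blood').  Expected VAFs are clamped to
    [seq_error / 3, 0.5] so absent markers retain the sequencing-error
    floor.
    """
    sample = blood_counts.attrs.get("sample", "blood")
    common = informative.index.intersection(blood_counts.index)
    common = common[blood_counts.loc[common, "depth"] > 0]
    if len(common) == 0:
        return MixingEstimate(sample, None, None, None, 0, "no_informative_eems")
    alt = blood_counts.loc[common, "alt"].to_numpy(dtype=int)
    depth = blood_counts.loc[common, "depth"].to_numpy(dtype=int)
    source = informative.loc[common, "source_twin"].to_numpy(dtype=int)
    err = seq_error / 3.0

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    ll = _loglik_grid(grid, alt, depth, source, err)
    i_best = int(np.argmax(ll))

    # golden-section refinement in the bracketing interval
    lo = grid[max(0, i_best - 1)]
    hi = grid[min(len(grid) - 1, i_best + 1)]
    res = minimize_scalar(
        lambda m: -_loglik_grid([m], alt, depth, source, err)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    m_hat = float(res.x)
    ll_max = float(-res.fun)

    # profile-likelihood 95% CI from the grid, linearly interpolated
    thresh = ll_max - PROFILE_DROP
    above = ll >= thresh
    if above.any():
        lo_i = int(np.argmax(above))
        hi_i = len(above) - 1 - int(np.argmax(above[::-1]))
        ci = (float(grid[lo_i]), float(grid[hi_i]))
    else:  # pathological flat likelihood
        ci = (0.0, 1.0)
    ci = (min(ci[0], m_hat), max(ci[1], m_hat))
    return MixingEstimate(sample, m_hat, ci, ll_max, int(len(common)), "ok")


def estimate_mixing_pooled(
    informative: pd.DataFrame,
    blood_counts_by_sample: dict[str, pd.DataFrame],
    seq_error: float = 0.001,
    grid_step: float = 1e-3,
) -> MixingEstimate:
    """Single mixing fraction fitted jointly to both co-twins' cord bloods.

    Monochorionic cord bloods are drawn from one well-mixed pool, so a
    pooled fit is also provided; the per-sample mode remains the default.
    """
    frames = []
    for name, bc in blood_counts_by_sample.items():
        common = informative.index.intersection(bc.index)
        sub = bc.loc[common, ["depth", "alt"]].copy()
        sub["source_twin"] = informative.loc[common, "source_twin"]
        frames.append(sub)
    merged = pd.concat(frames, ignore_index=True)  # one row per (EEM, sample)
    merged = merged[merged["depth"] > 0]
    if len(merged) == 0:
        return MixingEstimate("pooled", None, None, None, 0, "no_informative_eems")
    counts = merged[["depth", "alt"]]
    counts.attrs["sample"] = "pooled"
    info = merged[["source_twin"]]
    return estimate_mixing(info, counts, seq_error=seq_error, grid_step=grid_step)
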
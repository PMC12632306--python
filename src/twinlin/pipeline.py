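"""End-to-end cohort pipeline: simulate -> call -> fit -> classify -> chimerism -> stats.

Given a cohort configuration and a seed, the pipeline simulates the twin
cohort, classifies variants against the parental trio, fits the two-lineage
anchor model per monozygotic pair, estimates cord-blood mixing where blood
is available, runs the cohort-level association tests, and writes a report
with one row per family plus a recovery summary against the simulation
truth.  Per-family failures are recorded and do not stop the run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .anchor_model import (
    AnchorFitError,
    ModelConfig,
    divisions_between_founders,
    fit_pair,
    genetic_distance,
)
from .chimerism import estimate_mixing, select_informative
from .cohort_stats import fisher_montecarlo, kruskal_wallis_bonferroni
from .eem_calling import classify_variants, pair_summary, refine_with_targeted
from .synthetic_embryo import CohortBundle, CohortConfig, simulate_cohort, write_cohort

log = logging.getLogger("twinlin")

CLONAL_MIN_VAF = 0.4  # buccal VAF above which an EEM counts as clonal in a twin
ABSENT_MAX_VAF = 0.02
# genetic distance counts near-clonal sublineage events (cell fraction
# >= 0.4); lower thresholds are dominated by deep subclonal EEMs whose
# apparent twin-uniqueness is a progenitor-sampling artifact
DISTANCE_MIN_VAF = 0.2


def _unique_clonal_count(vaf1: pd.Series, vaf2: pd.Series) -> int:
    """EEMs clonal in Twin 1's tissue and absent from Twin 2's."""
    v1 = vaf1.fillna(0).to_numpy()
    v2 = vaf2.fillna(0).to_numpy()
    return int(((v1 >= CLONAL_MIN_VAF) & (v2 <= ABSENT_MAX_VAF)).sum())


def analyze_mz_pair(
    table, family: str, targeted=None, model_config: ModelConfig | None = None
) -> dict:
    """Anchor-model analysis of one monozygotic pair's variant table.

    Classification runs on the discovery (WGS) counts; when a deep-targeted
    validation table is supplied its VAFs drive the anchor fit and clonal
    counts, mirroring the discovery-then-validation design.
    """
    model_config = model_config or ModelConfig()
    callset = classify_variants(table)
    if targeted is not None:
        callset = refine_with_targeted(callset, targeted)
    summary = pair_summary(callset)
    eems = callset.of_class("eem")
    vaf = (targeted or table).pivot("vaf")
    eems = eems.intersection(vaf.index)
    buccal = [s for s in table.samples if s.endswith("_buccal")]
    if len(buccal) != 2:
        raise ValueError(f"{family}: expected two buccal samples, got {buccal}")
    out: dict = {"family": family, **summary}
    pair_vafs = vaf.loc[eems, buccal].fillna(0.0)
    out["genetic_distance"] = (
        genetic_distance(pair_vafs >= DISTANCE_MIN_VAF) if len(pair_vafs) else 0
    )
    out["n_unique_clonal_twin1"] = _unique_clonal_count(
        pair_vafs[buccal[0]], pair_vafs[buccal[1]]
    )
    try:
        fit = fit_pair(
            pair_vafs.to_numpy(), model_config, ids=list(eems),
            twin_names=(buccal[0], buccal[1]),
        )
        out.update(
            a_hat=fit.a, b_hat=fit.b, category=fit.category,
            twin1_sample=fit.twin_order[0], qc_flags=";".join(fit.flags),
            anchor_n=(fit.anchor.size if fit.anchor else 0),
            counter_anchor_n=(fit.counter_anchor.size if fit.counter_anchor else 0),
        )
        n_uniq = _unique_clonal_count(
            pair_vafs[fit.twin_order[0]], pair_vafs[fit.twin_order[1]]
        )
        out["divisions_between_founders"] = divisions_between_founders(
            n_uniq, model_config.founder_rate
        )
    except AnchorFitError as exc:
        out.update(a_hat=np.nan, b_hat=np.nan, category="failed", qc_flags=str(exc))
    return out


def analyze_blood_mixing(table, family: str, targeted=None, seq_error: float = 0.001) -> dict:
    """Per-cord-blood-sample ML mixing estimates for one family."""
    deep = targeted or table
    vaf = deep.pivot("vaf")
    depth = deep.pivot("depth")
    alt = deep.pivot("alt")
    buccal = [s for s in table.samples if s.endswith("_buccal")]
    blood = [s for s in deep.samples if s.endswith("_cord_blood")]
    if len(blood) < 2 or len(buccal) != 2:
        return {}
    callset = classify_variants(table)
    if targeted is not None:
        callset = refine_with_targeted(callset, targeted)
    eems = callset.of_class("eem").intersection(vaf.index)
    informative = select_informative(
        vaf.loc[eems, buccal], CLONAL_MIN_VAF, ABSENT_MAX_VAF
    )
    out = {}
    for i, sample in enumerate(blood, start=1):
        counts = pd.DataFrame(
            {"depth": depth[sample].fillna(0).astype(int), "alt": alt[sample].fillna(0).astype(int)}
        )
        counts.attrs["sample"] = sample
        est = estimate_mixing(informative, counts, seq_error=seq_error)
        out[f"m_twin2_in_blood{i}"] = est.m
        out[f"mixing_ci_blood{i}"] = est.ci
        out[f"mixing_n_informative"] = est.n_informative
        out[f"mixing_status_blood{i}"] = est.status
    return out


def run_pipeline(
    config: CohortConfig | str | Path | None = None,
    seed: int = 0,
    outdir: str | Path = "twinlin_out",
    write_inputs: bool = True,
) -> pd.DataFrame:
    """Run the full cohort analysis; returns the cohort report DataFrame.

    Writes ``report.tsv``, per-family fit JSONs, ``stats.json`` and
    ``recovery.json`` under ``outdir``; with ``write_inputs`` also the
    simulated variant tables and truth record.
    """
    if isinstance(config, (str, Path)):
        config = CohortConfig.from_yaml(config)
    config = config or CohortConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulating cohort (seed=%d)", seed)
    bundle: CohortBundle = simulate_cohort(config, seed=seed)
    if write_inputs:
        write_cohort(bundle, out / "inputs", formats=("tsv",))

    rows = []
    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    for family, table in bundle.tables.items():
        truth = bundle.truth["families"][family]
        row: dict = {
            "family": family, "membrane": truth["membrane"],
            "zygosity": truth["zygosity"], "category_true": truth["category"],
        }
        try:
            if truth["zygosity"] == "DZ":
                callset = classify_variants(table)
                row.update(pair_summary(callset))
                row["category"] = "dizygotic"
            elif truth["category"] == "triplet":
                row.update(_analyze_triplet(table, family, bundle.targeted[family]))
            else:
                row.update(analyze_mz_pair(table, family, bundle.targeted[family]))
                row.update(
                    analyze_blood_mixing(
                        table, family, bundle.targeted[family], config.params.seq_error
                    )
                )
                row["tissue_category_true"] = truth.get("tissue_category")
                row["a_true"] = truth.get("buccal_a")
                row["b_true"] = truth.get("buccal_b")
                blood_f1 = truth.get("blood_twin1_fraction")
                if blood_f1 is not None:
                    for i, (name, f1) in enumerate(sorted(blood_f1.items()), start=1):
                        row[f"m_twin2_true_blood{i}"] = 1.0 - f1
        except Exception as exc:  # per-family failures must not stop the cohort
            log.exception("family %s failed", family)
            row["category"] = "failed"
            row["qc_flags"] = f"error:{exc}"
        rows.append(row)
        with open(fits_dir / f"{family}.json", "w") as fh:
            json.dump(row, fh, indent=1, default=_jsonable)

    report = pd.DataFrame(rows)
    report.to_csv(out / "report.tsv", sep="\t", index=False)

    stats = cohort_statistics(report, seed=seed)
    with open(out / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, default=_jsonable)
    recovery = recovery_summary(report)
    with open(out / "recovery.json", "w") as fh:
        json.dump(recovery, fh, indent=1, default=_jsonable)
    log.info("pipeline complete: %d families", len(report))
    return report


def _analyze_triplet(table, family: str, targeted=None) -> dict:
    """Pairwise anchor fits and founder topology for a triplet family."""
    from .anchor_model import triplet_topology

    buccal = [s for s in table.samples if s.endswith("_buccal")]
    if len(buccal) != 3:
        return {"category": "failed", "qc_flags": "triplet needs three buccal samples"}
    callset = classify_variants(table)
    if targeted is not None:
        callset = refine_with_targeted(callset, targeted)
    deep = (targeted or table).pivot("vaf")
    eems = callset.of_class("eem").intersection(deep.index)
    vaf = deep.loc[eems, buccal].fillna(0.0)
    fits, shared = {}, {}
    short = {s: s.split("_")[1] for s in buccal}  # e.g. F23_triplet1_buccal -> triplet1
    for i in range(3):
        for j in range(i + 1, 3):
            si, sj = buccal[i], buccal[j]
            key = (short[si], short[sj])
            clonal_i = vaf[si] >= CLONAL_MIN_VAF
            clonal_j = vaf[sj] >= CLONAL_MIN_VAF
            shared[key] = int((clonal_i & clonal_j).sum())
            try:
                fits[key] = fit_pair(
                    vaf[[si, sj]].to_numpy(), ids=list(vaf.index),
                    twin_names=(short[si], short[sj]),
                )
            except AnchorFitError:
                fits[key] = None
    if any(f is None for f in fits.values()):
        return {"category": "failed", "qc_flags": "pairwise anchor fit failed"}
    topo = triplet_topology(fits, shared)
    cats = {f"category_{a}_{b}": fits[(a, b)].category for (a, b) in fits}
    return {
        "category": "triplet", "topology": topo.newick,
        "topology_status": topo.status, **cats,
    }


def cohort_statistics(report: pd.DataFrame, seed: int = 0, B: int = 20_000) -> dict:
    """Membrane-type association tests over the monozygotic pairs.

    A membrane x category contingency test (Monte Carlo Fisher) and a
    Kruskal-Wallis comparison of genetic distances across membrane types,
    with Bonferroni-adjusted pairwise follow-ups.
    """
    mz = report[(report["zygosity"] == "MZ") & (report["category_true"] != "triplet")]
    mz = mz[mz["category"].isin(["para", "sub", "full"])]
    out: dict = {}
    if len(mz) >= 4 and mz["membrane"].nunique() >= 2:
        tab = pd.crosstab(mz["membrane"], mz["category"])
        res = fisher_montecarlo(tab.to_numpy(), B=B, seed=seed)
        out["category_vs_membrane"] = {
            "table": tab.to_dict(), "pvalue": res.pvalue, "B": res.B,
        }
    groups, labels = [], []
    for membrane, sub in mz.groupby("membrane"):
        d = sub["genetic_distance"].dropna()
        if len(d):
            groups.append(d.to_numpy(dtype=float))
            labels.append(membrane)
    if len(groups) >= 2:
        omnibus, pairwise = kruskal_wallis_bonferroni(groups)
        out["genetic_distance_kw"] = {
            "groups": labels, "H": omnibus.statistic, "pvalue": omnibus.pvalue,
            "pairwise": [
                {**p, "pair": (labels[p["pair"][0]], labels[p["pair"][1]])}
                for p in pairwise
            ],
        }
    return out


def recovery_summary(report: pd.DataFrame) -> dict:
    """Truth-recovery metrics for simulated cohorts."""
    mz = report[(report["zygosity"] == "MZ") & (report["category_true"] != "triplet")]
    out: dict = {"n_mz_pairs": int(len(mz))}
    fitted = mz[mz["category"].isin(["para", "sub", "full", "discordant"])]
    out["n_fitted"] = int(len(fitted))
    if len(fitted):
        out["category_accuracy"] = float(
            (fitted["category"] == fitted["category_true"]).mean()
        )
        if "tissue_category_true" in fitted:
            # accuracy against the category realized at the tissue level,
            # which is what the VAFs can actually resolve
            out["tissue_category_accuracy"] = float(
                (fitted["category"] == fitted["tissue_category_true"]).mean()
            )
        if "a_true" in fitted:
            ok = fitted.dropna(subset=["a_true", "a_hat"])
            if len(ok):
                out["a_rmse"] = float(
                    np.sqrt(np.mean((ok["a_hat"] - ok["a_true"]) ** 2))
                )
                out["b_rmse"] = float(
                    np.sqrt(np.mean((ok["b_hat"] - ok["b_true"]) ** 2))
                )
    errs = []
    for i in (1, 2):
        t, e = f"m_twin2_true_blood{i}", f"m_twin2_in_blood{i}"
        if t in report and e in report:
            ok = report.dropna(subset=[t, e])
            errs.append((ok[e] - ok[t]).to_numpy(dtype=float))
    if errs and len(np.concatenate(errs)):
        out["mixing_rmse"] = float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))
    return out


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    return str(o)
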
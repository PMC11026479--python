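"""Patient-level analytics: uTMB, expression outliers, survival grouping.

The untranslated tumor mutational burden (uTMB) of a patient counts their
somatic mutations that are functional variants in the screen, stratified
into six categories by cancer driver role and effect direction.  A variant
is detrimental when it increases an oncogene's or decreases a tumor
suppressor's expression; the opposite pattern is benign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

UTMB_COLUMNS = [
    "utmb_func_overall", "utmb_driver_func_overall",
    "utmb_driver_func_detrimental", "utmb_driver_func_benign",
    "utmb_nonfunc", "utmb_driver_nonfunc",
]


def classify_variant_effect(functional: bool, direction: str, driver_role: str) -> str:
    """detrimental / benign / ambiguous / none for one called variant."""
    if not functional:
        return "none"
    if driver_role == "oncogene":
        return "detrimental" if direction == "up" else "benign"
    if driver_role == "tsg":
        return "detrimental" if direction == "down" else "benign"
    return "ambiguous"


def annotate_effect(calls: pd.DataFrame) -> pd.DataFrame:
    """Adds an ``effect_class`` column from functional/direction/driver_role."""
    out = calls.copy()
    out["effect_class"] = [
        classify_variant_effect(bool(r.functional), r.direction, r.driver_role)
        for r in out.itertuples(index=False)
    ]
    return out


def compute_utmb(mutations: pd.DataFrame, calls: pd.DataFrame,
                 patients=None) -> pd.DataFrame:
    """Six per-patient uTMB counts from somatic mutations x screen calls.

    ``mutations`` has (patient_id, variant_id); ``calls`` must carry
    variant_id, functional, direction and driver_role.  Mutations absent
    from the calls table are ignored; patients without any overlap get all
    zeros (pass ``patients`` to include patients with no mutations).
    """
    ann = annotate_effect(calls).set_index("variant_id")
    if patients is None:
        patients = mutations["patient_id"].unique()
    rows = {p: dict.fromkeys(UTMB_COLUMNS, 0) for p in patients}
    for m in mutations.itertuples(index=False):
        if m.variant_id not in ann.index or m.patient_id not in rows:
            continue
        v = ann.loc[m.variant_id]
        r = rows[m.patient_id]
        is_driver = v.driver_role in ("oncogene", "tsg", "ambiguous")
        if v.functional:
            r["utmb_func_overall"] += 1
            if is_driver:
                r["utmb_driver_func_overall"] += 1
                if v.effect_class == "detrimental":
                    r["utmb_driver_func_detrimental"] += 1
                elif v.effect_class == "benign":
                    r["utmb_driver_func_benign"] += 1
        else:
            r["utmb_nonfunc"] += 1
            if is_driver:
                r["utmb_driver_nonfunc"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").reset_index(
        names="patient_id"
    )
    return df[["patient_id", *UTMB_COLUMNS]]


def tertile_groups(values: pd.Series) -> pd.Series:
    """Label patients high/mid/low by uTMB tertile within a cohort.

    Patients are ordered by (value, index) — the stable index order resolves
    boundary ties deterministically — and split into three positional thirds
    whose sizes differ by at most one.  Degenerate input (all values equal)
    returns a single 'mid' group.
    """
    if len(values) < 3:
        raise ValueError("tertile grouping needs >= 3 patients")
    if values.nunique() == 1:
        return pd.Series("mid", index=values.index)
    order = values.sort_values(kind="stable").index
    thirds = np.array_split(np.asarray(order), 3)
    labels = pd.Series(index=values.index, dtype=object)
    labels.loc[thirds[0]] = "low"
    labels.loc[thirds[1]] = "mid"
    labels.loc[thirds[2]] = "high"
    return labels


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-sided log-rank comparison of two survival groups.

    Each frame needs ``time`` and ``event`` columns.  Returns the chi-square
    statistic (1 df) and its two-sided p-value.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both survival groups must be non-empty")
    if int(group_a["event"].sum()) + int(group_b["event"].sum()) == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _lifelines_logrank(
        group_a["time"], group_b["time"],
        event_observed_A=group_a["event"].astype(bool),
        event_observed_B=group_b["event"].astype(bool),
    )
    return float(res.test_statistic), float(res.p_value)


def survival_by_utmb(
    utmb: pd.DataFrame,
    survival: pd.DataFrame,
    metric: str = "utmb_func_overall",
    grouping: str = "tertile",
) -> pd.DataFrame:
    """Per-cohort high-vs-low survival comparison for one uTMB category.

    ``grouping='tertile'`` compares the top against the bottom tertile with
    the middle excluded; ``'top_vs_rest'`` compares the top tertile against
    everyone else.  Cohorts whose uTMB is degenerate are skipped with a flag.
    """
    merged = survival.merge(utmb, on="patient_id", how="inner")
    rows = []
    for cohort, grp in merged.groupby("cohort"):
        vals = grp.set_index("patient_id")[metric]
        if len(vals) < 3 or vals.nunique() == 1:
            rows.append({"cohort": cohort, "metric": metric, "statistic": np.nan,
                         "p_value": np.nan, "n_high": 0, "n_low": 0,
                         "skipped": True})
            continue
        labels = tertile_groups(vals)
        g = grp.set_index("patient_id")
        high = g.loc[labels[labels == "high"].index]
        if grouping == "tertile":
            low = g.loc[labels[labels == "low"].index]
        elif grouping == "top_vs_rest":
            low = g.loc[labels[labels != "high"].index]
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        stat, p = logrank_test(high, low)
        rows.append({"cohort": cohort, "metric": metric, "statistic": stat,
                     "p_value": p, "n_high": len(high), "n_low": len(low),
                     "skipped": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression outliers
# ---------------------------------------------------------------------------

def detect_outliers(
    expression: pd.DataFrame,
    mutations: pd.DataFrame,
    calls: pd.DataFrame,
    min_reference: int = 5,
    z_cut: float = 2.0,
) -> pd.DataFrame:
    """Expression z-scores of variant carriers against non-carrier baselines.

    For each called variant with a ``gene`` column entry, carriers are
    patients bearing the mutation and the reference group is every other
    patient; the carrier z-score uses the reference group's mean/sd.  A
    carrier is an outlier when |z| > ``z_cut``; ``consistent`` records
    whether sign(z) matches sign(lnFC).  Genes with fewer than
    ``min_reference`` reference patients or zero reference sd are skipped.
    """
    carriers_by_variant = mutations.groupby("variant_id")["patient_id"].apply(set)
    rows = []
    for call in calls.itertuples(index=False):
        gene = getattr(call, "gene", None)
        if gene is None or gene not in expression.columns:
            continue
        carriers = carriers_by_variant.get(call.variant_id, set())
        carriers = [p for p in carriers if p in expression.index]
        if not carriers:
            continue
        ref_patients = expression.index.difference(carriers)
        if len(ref_patients) < min_reference:
            continue
        ref = expression.loc[ref_patients, gene]
        sd = float(ref.std(ddof=1))
        if sd == 0:
            continue
        mean = float(ref.mean())
        for p in sorted(carriers):
            z = (float(expression.loc[p, gene]) - mean) / sd
            rows.append({
                "variant_id": call.variant_id, "gene": gene, "patient_id": p,
                "z": z, "outlier": abs(z) > z_cut,
                "consistent": np.sign(z) == np.sign(call.lnFC),
            })
    return pd.DataFrame(rows, columns=["variant_id", "gene", "patient_id", "z",
                                       "outlier", "consistent"])


def outlier_proportion_test(
    n_carrier_outliers: int, n_carriers: int,
    n_ref_outliers: int, n_refs: int,
) -> tuple[float, float]:
    """Two-sided Fisher exact on the carrier-vs-reference outlier 2x2 table.

    Returns (odds ratio, p); an empty margin yields p = 1 with OR = NaN.
    """
    table = [[n_carrier_outliers, n_carriers - n_carrier_outliers],
             [n_ref_outliers, n_refs - n_ref_outliers]]
    flat = np.array(table)
    if (flat.sum(axis=0) == 0).any() or (flat.sum(axis=1) == 0).any():
        return np.nan, 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def cooccurrence_counts(mutations: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Functional-variant co-occurrence per (patient, gene) with direction
    breakdown (how many up- vs down-regulating variants co-occur)."""
    func = calls[calls["functional"]].set_index("variant_id")
    uniq = mutations.drop_duplicates(subset=["patient_id", "variant_id"])
    rows = []
    for m in uniq.itertuples(index=False):
        if m.variant_id in func.index:
            v = func.loc[m.variant_id]
            rows.append({"patient_id": m.patient_id, "gene": v.get("gene", ""),
                         "variant_id": m.variant_id, "direction": v.direction})
    if not rows:
        return pd.DataFrame(columns=["patient_id", "gene", "n_variants",
                                     "n_up", "n_down"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["patient_id", "gene"])
        .agg(n_variants=("variant_id", "nunique"),
             n_up=("direction", lambda d: int((d == "up").sum())),
             n_down=("direction", lambda d: int((d == "down").sum())))
        .reset_index()
    )
    return out
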
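"""Mislabelling adjudication, rate estimation, and the regime sensitivity
analysis.

A product is *mislabelled* under a definition regime when the DNA-assigned
species falls outside the set of species its written label (maximum level
of detail) may legitimately denote under that regime.  Products without a
species assignment are *unassessable* and leave the denominators.  Coarse
labels are judged against their own permitted set — a "tuna"-labelled
product matching any listed scombrid is correct; the species-level
counterfactual is the business of the censored-standardisation model, not
of adjudication.  Pure generic labels ("fish") resolve to the universal set,
can never be mislabelled, and stay in denominators.

Rates come with Wald 95% intervals; multinomial category breakdowns (e.g.
specificity shares) use Goodman's simultaneous chi-square intervals.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .label_reference import SPECIFICITY_NAMES, LabelReference

__all__ = [
    "adjudicate",
    "adjudicate_cohort",
    "mislabelling_rates",
    "sensitivity_analysis",
    "goodman_intervals",
    "vendor_comparison",
    "annotate_conservation",
    "wald_interval",
]

CORRECT, MISLABELLED, UNASSESSABLE = "correct", "mislabelled", "unassessable"


def adjudicate(
    label_max_detail: str,
    assigned_species: str | None,
    reference: LabelReference,
    regime: str,
) -> tuple[str, str]:
    """Status of one product under one regime: ``(status, reason)``.

    ``unassessable`` when no species was assigned, or when the label term is
    unknown to the reference table (reason ``"unknown_term"`` — surfaced,
    never silently counted as mislabelled).  Pure function of its inputs.
    """
    if assigned_species is None or (isinstance(assigned_species, float)) or not str(assigned_species).strip():
        return UNASSESSABLE, "not_assigned"
    res = reference.resolve(label_max_detail, regime)
    if res.unknown_term:
        return UNASSESSABLE, "unknown_term"
    acc = reference.accepted_name(assigned_species)
    if acc is None:
        return UNASSESSABLE, "species_not_in_taxonomy"
    return (CORRECT, "") if acc in res.species else (MISLABELLED, "")


def adjudicate_cohort(
    products: pd.DataFrame,
    calls: pd.DataFrame,
    reference: LabelReference,
    regimes: tuple[str, ...] = ("comprehensive",),
) -> pd.DataFrame:
    """Adjudicate every product under every regime.

    Joins the species-call table on ``sample_id`` and returns one row per
    product with ``specificity`` (ordinal, from the comprehensive regime),
    a ``status_<regime>`` column per regime, and vendor agreement.
    """
    merged = products.merge(
        calls[["sample_id", "status", "species"]], on="sample_id", how="left"
    )
    rows = []
    for row in merged.itertuples(index=False):
        assigned = row.species if row.status == "assigned" else None
        spec = reference.label_specificity(row.label_max_detail, "comprehensive")
        rec = {
            "sample_id": row.sample_id,
            "specificity": spec,
            "specificity_name": SPECIFICITY_NAMES.get(spec, "unknown"),
            "assigned_species": assigned,
            "call_status": row.status if isinstance(row.status, str) else "no_amplification",
        }
        for regime in regimes:
            status, reason = adjudicate(row.label_max_detail, assigned, reference, regime)
            rec[f"status_{regime}"] = status
            rec[f"reason_{regime}"] = reason
        claim = getattr(row, "vendor_claim", "")
        if assigned is None or not isinstance(claim, str) or not claim.strip():
            rec["vendor_agreement"] = "absent"
        else:
            vres = reference.resolve(claim, regimes[0])
            acc = reference.accepted_name(assigned)
            rec["vendor_agreement"] = (
                "agree" if (vres.species and acc in vres.species) else "disagree"
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    carry = [
        c
        for c in (
            "state",
            "outlet_type",
            "seafood_group",
            "origin",
            "label_max_detail",
            "vendor_claim",
            "price_per_kg",
            "wild_or_farmed",
            "fresh_or_frozen",
            "packaged",
            "certified",
        )
        if c in products.columns
    ]
    return out.merge(products[["sample_id"] + carry], on="sample_id")


def wald_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wald 95% CI for a proportion, truncated to [0, 1]."""
    lo, hi = proportion_confint(k, n, alpha=alpha, method="normal")
    return max(0.0, float(lo)), min(1.0, float(hi))


def _rate_row(sub: pd.DataFrame, status_col: str, stratum: str, alpha: float) -> dict | None:
    assessed = sub[sub[status_col] != UNASSESSABLE]
    n = len(assessed)
    if n == 0:
        return None
    k = int((assessed[status_col] == MISLABELLED).sum())
    lo, hi = wald_interval(k, n, alpha)
    return {
        "stratum": stratum,
        "numerator": k,
        "denominator": n,
        "proportion": 100.0 * k / n,
        "ci_low": 100.0 * lo,
        "ci_high": 100.0 * hi,
        "method": "wald",
    }


def mislabelling_rates(
    adjudicated: pd.DataFrame,
    regime: str = "comprehensive",
    stratifiers: tuple[str, ...] = ("overall",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mislabelling rate table with Wald CIs.

    ``stratifiers`` may include ``overall``, ``seafood_group``, ``origin``,
    ``outlet_type``, ``specificity_name``, ``state``.  Unassessable products
    are excluded from denominators; empty strata are absent.
    """
    col = f"status_{regime}"
    if col not in adjudicated.columns:
        raise ValueError(f"regime {regime!r} not adjudicated")
    rows = []
    for strat in stratifiers:
        if strat == "overall":
            r = _rate_row(adjudicated, col, "overall", alpha)
            if r:
                rows.append(r)
        else:
            for val, sub in adjudicated.groupby(strat):
                r = _rate_row(sub, col, f"{strat}={val}", alpha)
                if r:
                    rows.append(r)
    out = pd.DataFrame(rows)
    out.insert(0, "regime", regime)
    return out


def sensitivity_analysis(
    adjudicated: pd.DataFrame,
    regimes: tuple[str, ...] = ("comprehensive", "afns", "strict_flake", "lenient_flake"),
    group_col: str = "seafood_group",
) -> pd.DataFrame:
    """Regime x seafood-group mislabelling table (plus an overall column).

    All regimes must be adjudicated on the identical sample set.  Verifies
    the structural monotonicity strict_flake >= comprehensive >=
    lenient_flake on the overall rate: shrinking a permitted set can only
    create mislabelling, enlarging it can only remove it.
    """
    for regime in regimes:
        if f"status_{regime}" not in adjudicated.columns:
            raise ValueError(f"regime {regime!r} not adjudicated on this cohort")
    denoms = {
        regime: set(
            adjudicated.loc[
                adjudicated[f"status_{regime}"] != UNASSESSABLE, "sample_id"
            ]
        )
        for regime in regimes
    }
    base = denoms[regimes[0]]
    for regime in regimes[1:]:
        if denoms[regime] != base:
            raise ValueError(
                f"regime {regime!r} covers a different sample set than {regimes[0]!r}"
            )
    rows = []
    for regime in regimes:
        col = f"status_{regime}"
        assessed = adjudicated[adjudicated[col] != UNASSESSABLE]
        rec = {"regime": regime}
        rec["overall"] = 100.0 * (assessed[col] == MISLABELLED).mean()
        for grp, sub in assessed.groupby(group_col):
            rec[str(grp)] = 100.0 * (sub[col] == MISLABELLED).mean()
        rows.append(rec)
    table = pd.DataFrame(rows).set_index("regime")
    have = set(table.index)
    if {"comprehensive", "strict_flake"} <= have:
        assert table.loc["strict_flake", "overall"] >= table.loc["comprehensive", "overall"] - 1e-9
    if {"comprehensive", "lenient_flake"} <= have:
        assert table.loc["lenient_flake", "overall"] <= table.loc["comprehensive", "overall"] + 1e-9
    return table


def goodman_intervals(counts, alpha: float = 0.05) -> pd.DataFrame:
    """Goodman (1965) simultaneous CIs for multinomial proportions.

    For k categories with counts n_i summing to N, each bound uses the
    Bonferroni-adjusted chi-square quantile A = chi2.ppf(1 - alpha/k, 1):

        (A + 2 n_i -/+ sqrt(A (A + 4 n_i (N - n_i) / N))) / (2 (N + A))

    Bounds are clipped to [0, 1]; the set of k intervals covers the whole
    proportion vector simultaneously at >= 1 - alpha (asymptotically).
    """
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("total count is zero")
    k = len(counts)
    a = float(stats.chi2.ppf(1 - alpha / k, df=1))
    rows = []
    for n_i in counts:
        half = (a * (a + 4.0 * n_i * (total - n_i) / total)) ** 0.5
        lo = (a + 2.0 * n_i - half) / (2.0 * (total + a))
        hi = (a + 2.0 * n_i + half) / (2.0 * (total + a))
        rows.append(
            {
                "count": n_i,
                "proportion": n_i / total,
                "ci_low": max(0.0, lo),
                "ci_high": min(1.0, hi),
                "method": "goodman",
            }
        )
    return pd.DataFrame(rows)


def vendor_comparison(
    adjudicated: pd.DataFrame,
    reference: LabelReference,
    regime: str = "comprehensive",
) -> dict:
    """Compare vendor verbal claims against the molecular identification.

    Counts agree/disagree/absent, plus ``rescued``: products mislabelled on
    the written label whose vendor claim would have covered the assigned
    species.  Purely descriptive — the primary adjudication (written label
    only) is never altered.
    """
    col = f"status_{regime}"
    counts = adjudicated["vendor_agreement"].value_counts().to_dict()
    rescued = 0
    with_claim = adjudicated[
        (adjudicated["vendor_agreement"] != "absent")
        & (adjudicated[col] == MISLABELLED)
    ]
    for row in with_claim.itertuples(index=False):
        vres = reference.resolve(row.vendor_claim, regime)
        acc = reference.accepted_name(row.assigned_species)
        if vres.species and acc in vres.species:
            rescued += 1
    n_claimed = int(
        (adjudicated["vendor_agreement"] != "absent").sum()
    )
    disagree = int(counts.get("disagree", 0))
    return {
        "agree": int(counts.get("agree", 0)),
        "disagree": disagree,
        "absent": int(counts.get("absent", 0)),
        "rescued": rescued,
        "pct_incorrect_of_claimed": (100.0 * disagree / n_claimed) if n_claimed else float("nan"),
    }


def annotate_conservation(
    adjudicated: pd.DataFrame, status_table: pd.DataFrame, reference: LabelReference
) -> pd.DataFrame:
    """Left-join a species -> conservation-category table onto the results.

    Joins on accepted species names (synonym-safe); species absent from the
    table are annotated ``unknown``.  Key-exact: row order of the status
    table is irrelevant.
    """
    out = adjudicated.copy()
    mapping = {}
    if len(status_table):
        for row in status_table.itertuples(index=False):
            acc = reference.accepted_name(row.species)
            if acc is not None:
                mapping[acc] = str(row.category)
    out["conservation_status"] = [
        mapping.get(reference.accepted_name(s) if isinstance(s, str) else None, "unknown")
        for s in out["assigned_species"]
    ]
    return out
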
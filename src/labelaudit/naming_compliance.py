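"""Misnaming: does the label use an approved AFNS standard fish name?

Misnaming is orthogonal to mislabelling — a biologically accurate label can
still use a non-approved name (e.g. "calamari", which the standard does not
recognise on its own), and an approved name can sit on a substituted
product.  Nothing here reads or writes mislabelling state.

A product is correctly named when the normalised maximum-detail string OR
main label is within a small optimal-string-alignment distance (default 2)
of an approved name, or when it carries a valid scientific binomial.
"""

from __future__ import annotations

import re

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .label_reference import LabelReference, normalise_label

__all__ = [
    "StandardNameList",
    "osa_distance",
    "is_misnamed",
    "flag_misnaming",
    "misnaming_rate",
]

_BINOMIAL_PATTERN = re.compile(r"\b[A-Z][a-z]{2,}\s+[a-z]{3,}\b")


def osa_distance(a: str, b: str, cap: int | None = None) -> int:
    """Optimal string alignment distance (edits + adjacent transpositions).

    Unlike full Damerau-Levenshtein, no substring is edited more than once.
    ``cap`` allows early exit once the distance provably exceeds it.
    """
    la, lb = len(a), len(b)
    if cap is not None and abs(la - lb) > cap:
        return cap + 1
    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        if cap is not None and min(cur) > cap:
            return cap + 1
        prev2, prev = prev, cur
    return prev[lb]


class StandardNameList:
    """Approved standard names, pre-normalised like label terms."""

    def __init__(self, names):
        if isinstance(names, pd.DataFrame):
            names = names.iloc[:, 0].tolist()
        self.names = sorted({normalise_label(n) for n in names if str(n).strip()})
        if not self.names:
            raise ValueError("standard name list is empty")

    @classmethod
    def from_csv(cls, path) -> "StandardNameList":
        return cls(pd.read_csv(path))

    def best_match(self, term: str, max_distance: int) -> tuple[str | None, int]:
        """Closest approved name within ``max_distance``, else (None, inf)."""
        best, best_d = None, max_distance + 1
        for name in self.names:
            d = osa_distance(term, name, cap=best_d - 1)
            if d < best_d:
                best, best_d = name, d
                if d == 0:
                    break
        return best, best_d


def _has_binomial(raw: str, reference: LabelReference | None) -> bool:
    # with a taxonomy available, "valid" means resolvable (incl. synonyms);
    # otherwise fall back to the Latin-binomial shape
    if reference is not None:
        return reference.contains_binomial(raw) is not None
    return bool(_BINOMIAL_PATTERN.search(str(raw)))


def is_misnamed(
    label_main: str,
    label_max_detail: str,
    names: StandardNameList,
    max_distance: int = 2,
    reference: LabelReference | None = None,
) -> tuple[bool, str | None]:
    """Return ``(misnamed, matched_name)`` for one product.

    Either label string matching an approved name (within ``max_distance``
    OSA edits) or containing a scientific binomial counts as correctly
    named.  Decreasing ``max_distance`` can only move products towards
    misnamed, never the reverse.
    """
    for raw in (label_max_detail, label_main):
        if not raw or not str(raw).strip():
            continue
        if _has_binomial(raw, reference):
            return False, str(raw).strip()
        term = reference.normalise(raw) if reference else normalise_label(raw)
        match, d = names.best_match(term, max_distance)
        if match is not None and d <= max_distance:
            return False, match
    return True, None


def flag_misnaming(
    products: pd.DataFrame,
    names: StandardNameList,
    max_distance: int = 2,
    reference: LabelReference | None = None,
) -> pd.DataFrame:
    """Append a boolean ``misnamed`` column to the product table."""
    flags = [
        is_misnamed(
            row.label_main, row.label_max_detail, names, max_distance, reference
        )[0]
        for row in products.itertuples(index=False)
    ]
    out = products.copy()
    out["misnamed"] = flags
    return out


def misnaming_rate(
    flagged: pd.DataFrame, by: str | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Misnaming proportion with Wald CI, overall or per stratum.

    Strata with no products are absent from the output rather than
    reported as zero.
    """
    if "misnamed" not in flagged.columns:
        raise ValueError("run flag_misnaming first")

    def one(sub: pd.DataFrame, label: str) -> dict:
        n = len(sub)
        k = int(sub["misnamed"].sum())
        lo, hi = proportion_confint(k, n, alpha=alpha, method="normal")
        return {
            "stratum": label,
            "numerator": k,
            "denominator": n,
            "proportion": 100.0 * k / n,
            "ci_low": 100.0 * max(0.0, lo),
            "ci_high": 100.0 * min(1.0, hi),
            "method": "wald",
        }

    rows = [one(flagged, "overall")]
    if by is not None:
        for val, sub in flagged.groupby(by):
            if len(sub):
                rows.append(one(sub, str(val)))
    return pd.DataFrame(rows)
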
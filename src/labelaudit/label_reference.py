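"""Label-to-species reference tables, name normalisation, and label specificity.

A seafood market label ("flake", "snapper", "Thunnus thynnus") denotes a set of
species.  Which set depends on the *definition regime* in force: the
comprehensive regime of this package's main analysis, the stricter AFNS
(Australian Fish Names Standard) definitions, or the strict/lenient variants
of the contested term "flake".  This module holds the reference tables, turns
arbitrary label strings into canonical terms (resolving synonyms such as
*Melicertus plebejus* -> *Penaeus plebejus*), and classifies each label's
taxonomic specificity: the finest rank the permitted set pins down.

Specificity is coded ordinally: 1 = higher-than-family, 2 = family,
3 = genus, 4 = species.  A label permitting a single species is species
level; a multi-family set (or a pure generic such as "fish") is level 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SPECIFICITY_CODES",
    "SPECIFICITY_NAMES",
    "UNIVERSAL",
    "LabelReference",
    "normalise_label",
]

#: ordinal codes, coarse to fine
SPECIFICITY_CODES = {"higher": 1, "family": 2, "genus": 3, "species": 4}
SPECIFICITY_NAMES = {v: k for k, v in SPECIFICITY_CODES.items()}

#: sentinel species value meaning "every species in the taxonomy"
#: (used for pure generics like "fish" or "fillet")
UNIVERSAL = "*"

_WS_PUNCT = re.compile(r"[^a-z0-9]+")
_BINOMIAL = re.compile(r"^[A-Z][a-z]+ [a-z]{3,}$")


class UnknownRegimeError(KeyError):
    """Raised when a definition regime is not present in the label table."""


def normalise_label(raw: str) -> str:
    """Normalise a raw label string to a canonical lookup term.

    Lowercases, collapses punctuation and whitespace, and strips a trailing
    plural "s" from tokens (``"Gummy  Sharks" -> "gummy shark"``).  Tokens
    ending in "ss" or shorter than four characters are left alone.  Synonym
    resolution of scientific names is taxonomy-dependent and therefore lives
    on :meth:`LabelReference.normalise`.
    """
    if not raw or not str(raw).strip():
        raise ValueError("label string is empty")
    s = _WS_PUNCT.sub(" ", str(raw).lower()).strip()
    toks = []
    for t in s.split():
        if len(t) >= 4 and t.endswith("s") and not t.endswith("ss"):
            t = t[:-1]
        toks.append(t)
    return " ".join(toks)


def _split_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    return [v.strip() for v in str(value).split(";") if v.strip()]


@dataclass
class ResolvedLabel:
    """Outcome of resolving one label term under one regime."""

    term: str
    regime: str
    species: frozenset[str]
    unknown_term: bool = False

    @property
    def is_universal(self) -> bool:
        return False  # overwritten by LabelReference.resolve when applicable


@dataclass
class LintReport:
    orphan_species: list[str] = field(default_factory=list)
    unknown_species: list[str] = field(default_factory=list)
    duplicate_entries: list[tuple] = field(default_factory=list)
    regime_inconsistencies: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (
            self.orphan_species
            or self.unknown_species
            or self.duplicate_entries
            or self.regime_inconsistencies
        )


class LabelReference:
    """Taxonomy plus label->species definition tables for a set of regimes.

    Parameters
    ----------
    label_table:
        Long-format table with columns ``term, regime, species`` — one row
        per permitted species per term per regime.  ``species`` may be the
        ``"*"`` sentinel for pure generic terms.
    taxonomy:
        Table with columns ``species, genus, family, tags, synonyms``;
        ``tags`` and ``synonyms`` are ``;``-separated.

    Synonyms are resolved at load time; all downstream comparison happens on
    accepted names (lowercased).
    """

    FLAKE_REGIMES = ("strict_flake", "lenient_flake")

    def __init__(self, label_table: pd.DataFrame, taxonomy: pd.DataFrame):
        need = {"term", "regime", "species"}
        if not need.issubset(label_table.columns):
            raise ValueError(f"label table needs columns {sorted(need)}")
        need_t = {"species", "genus", "family"}
        if not need_t.issubset(taxonomy.columns):
            raise ValueError(f"taxonomy needs columns {sorted(need_t)}")

        self.taxonomy = taxonomy.reset_index(drop=True).copy()
        self._genus: dict[str, str] = {}
        self._family: dict[str, str] = {}
        self._tags: dict[str, frozenset[str]] = {}
        self._accepted: dict[str, str] = {}  # normalised name/synonym -> accepted
        for row in self.taxonomy.itertuples(index=False):
            sp = str(row.species).strip()
            key = sp.lower()
            if key in self._genus:
                raise ValueError(f"duplicate taxonomy species {sp!r}")
            self._genus[key] = str(row.genus).strip().lower()
            self._family[key] = str(row.family).strip().lower()
            tags = frozenset(
                t.lower() for t in _split_multi(getattr(row, "tags", None))
            )
            if {"selachimorph", "holocephalan"} <= tags:
                raise ValueError(f"{sp}: selachimorph and holocephalan are exclusive")
            self._tags[key] = tags
            self._accepted[key] = key
            for syn in _split_multi(getattr(row, "synonyms", None)):
                self._accepted[syn.lower()] = key

        self.all_species: frozenset[str] = frozenset(self._genus)

        self._sets: dict[tuple[str, str], frozenset[str]] = {}
        self._universal: set[tuple[str, str]] = set()
        tab = label_table.copy()
        tab["term"] = tab["term"].map(normalise_label)
        self.regimes: tuple[str, ...] = tuple(sorted(tab["regime"].unique()))
        for (term, regime), grp in tab.groupby(["term", "regime"]):
            raw_species = [str(s).strip() for s in grp["species"]]
            if UNIVERSAL in raw_species:
                self._sets[(term, regime)] = self.all_species
                self._universal.add((term, regime))
                continue
            resolved = set()
            for s in raw_species:
                acc = self._accepted.get(s.lower())
                if acc is None:
                    raise ValueError(
                        f"label table species {s!r} (term {term!r}, regime "
                        f"{regime!r}) is not in the taxonomy"
                    )
                resolved.add(acc)
            self._sets[(term, regime)] = frozenset(resolved)

    # ------------------------------------------------------------------ io

    @classmethod
    def from_csv(cls, label_csv, taxonomy_csv) -> "LabelReference":
        return cls(pd.read_csv(label_csv), pd.read_csv(taxonomy_csv))

    # ------------------------------------------------------- normalisation

    def accepted_name(self, name: str) -> str | None:
        """Accepted (lowercased) species name for a name or synonym, else None."""
        return self._accepted.get(str(name).strip().lower())

    def normalise(self, raw: str) -> str:
        """Normalise a label string, resolving scientific-name synonyms.

        A string that (case-insensitively) matches a taxonomy species or
        synonym resolves to the accepted name before plural stripping is
        attempted, so Latin epithets are never mangled.
        """
        acc = self.accepted_name(raw)
        if acc is not None:
            return acc
        return normalise_label(raw)

    def contains_binomial(self, raw: str) -> str | None:
        """Return the accepted species name if ``raw`` contains a valid
        scientific binomial (as a 2-token window resolvable in the taxonomy),
        else None."""
        toks = re.sub(r"[^A-Za-z ]+", " ", str(raw)).split()
        for i in range(len(toks) - 1):
            acc = self.accepted_name(f"{toks[i]} {toks[i + 1]}")
            if acc is not None:
                return acc
        return None

    # ----------------------------------------------------------- resolution

    def resolve(self, term: str, regime: str) -> ResolvedLabel:
        """Permitted species set for a (normalised) term under a regime.

        Unknown terms return an empty set with ``unknown_term=True`` — they
        are surfaced, never silently treated as mislabelled.
        """
        if regime not in self.regimes:
            raise UnknownRegimeError(
                f"unknown regime {regime!r}; configured: {self.regimes}"
            )
        t = self.normalise(term)
        key = (t, regime)
        if key in self._sets:
            out = ResolvedLabel(t, regime, self._sets[key])
        else:
            acc = self.accepted_name(t) or self.contains_binomial(term)
            if acc is not None:
                out = ResolvedLabel(t, regime, frozenset({acc}))
            else:
                out = ResolvedLabel(t, regime, frozenset(), unknown_term=True)
        return out

    def is_universal(self, term: str, regime: str) -> bool:
        return (self.normalise(term), regime) in self._universal

    # ----------------------------------------------------------- specificity

    def classify_specificity(self, species: frozenset[str] | set[str]) -> int | None:
        """Ordinal specificity of a permitted set (4=species ... 1=higher).

        The level is the finest rank shared by every species in the set.
        Empty sets are unclassifiable and return ``None``.
        """
        if not species:
            return None
        sps = {self._accepted.get(str(s).lower(), str(s).lower()) for s in species}
        unknown = sps - self.all_species
        if unknown:
            raise ValueError(f"species not in taxonomy: {sorted(unknown)}")
        if len(sps) == 1:
            return SPECIFICITY_CODES["species"]
        if len({self._genus[s] for s in sps}) == 1:
            return SPECIFICITY_CODES["genus"]
        if len({self._family[s] for s in sps}) == 1:
            return SPECIFICITY_CODES["family"]
        return SPECIFICITY_CODES["higher"]

    def label_specificity(self, raw_label: str, regime: str = "comprehensive") -> int | None:
        res = self.resolve(raw_label, regime)
        return self.classify_specificity(res.species) if res.species else None

    def species_with_tag(self, tag: str) -> frozenset[str]:
        tag = tag.lower()
        return frozenset(s for s, tags in self._tags.items() if tag in tags)

    def tags_of(self, species: str) -> frozenset[str]:
        acc = self.accepted_name(species)
        return self._tags.get(acc, frozenset()) if acc else frozenset()

    def terms(self, regime: str) -> list[str]:
        return sorted(t for (t, r) in self._sets if r == regime)

    # ----------------------------------------------------------------- lint

    def lint(self) -> LintReport:
        """Audit the tables: orphan species, duplicates, regime drift.

        Regime drift: the strict/lenient flake regimes must differ from the
        comprehensive regime only on the term "flake".
        """
        rep = LintReport()
        reachable = set()
        for key, sps in self._sets.items():
            reachable |= sps
        rep.orphan_species = sorted(self.all_species - reachable)

        seen = set()
        for (term, regime), sps in self._sets.items():
            for s in sps:
                if (term, regime, s) in seen:
                    rep.duplicate_entries.append((term, regime, s))
                seen.add((term, regime, s))

        if "comprehensive" in self.regimes:
            comp = {t: s for (t, r), s in self._sets.items() if r == "comprehensive"}
            for reg in self.FLAKE_REGIMES:
                if reg not in self.regimes:
                    continue
                other = {t: s for (t, r), s in self._sets.items() if r == reg}
                for t in set(comp) | set(other):
                    if t == "flake":
                        continue
                    if comp.get(t) != other.get(t):
                        rep.regime_inconsistencies.append(
                            f"term {t!r} differs between comprehensive and {reg}"
                        )
            if "strict_flake" in self.regimes:
                flake = self._sets.get(("flake", "strict_flake"), frozenset())
                want = {"mustelus antarcticus", "mustelus lenticulatus"}
                if flake and set(flake) != want:
                    rep.regime_inconsistencies.append(
                        "strict_flake 'flake' must be exactly the two Mustelus species"
                    )
        return rep
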
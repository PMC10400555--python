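"""Synthetic market-survey generator with the study's statistical structure.

Emulates a national seafood-labelling audit: 7 states x 96 products across
six seafood groups (hoki, prawns, sharks and rays, snapper, squid and
cuttlefish, tuna), three outlet types, an exact 50:50 domestic:imported
split, four label-specificity levels with group-specific mixes, and
group-by-level substitution probabilities.  Alongside the product table it
emits the ground truth (which products were substituted, and with what), a
toy COI-like reference sequence database, paired Sanger reads with Phred
qualities, and BLAST-outfmt-6-like hit tables — so the whole downstream
pipeline runs with no network access.

Everything is deterministic given the design seed: the same
:class:`StudyDesign` regenerates byte-identical outputs.

Stratum allocation (state x group, origin, outlet, specificity) uses
largest-remainder rounding with lexicographic tie-breaks, so integer counts
match the design exactly for every seed; only the per-product draws (label
term, species, substitution, price) are random.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .label_reference import SPECIFICITY_CODES, LabelReference

__all__ = [
    "StudyDesign",
    "ConfigurationError",
    "demo_taxonomy",
    "demo_label_table",
    "demo_afns_list",
    "demo_reference",
    "generate_products",
    "generate_refdb",
    "generate_reads",
    "generate_hit_table",
    "generate_hit_tables",
    "write_fastq",
]

GROUPS = (
    "hoki",
    "prawns",
    "sharks and rays",
    "snapper",
    "squid and cuttlefish",
    "tuna",
)
STATES = ("NSW", "NT", "QLD", "SA", "TAS", "VIC", "WA")
OUTLETS = ("fishmonger", "restaurant", "supermarket")

#: group shares of the 672-product survey (106, 116, 97, 112, 128, 113)
_GROUP_MIX = {
    "hoki": 106 / 672,
    "prawns": 116 / 672,
    "sharks and rays": 97 / 672,
    "snapper": 112 / 672,
    "squid and cuttlefish": 128 / 672,
    "tuna": 113 / 672,
}

#: outlet shares (196 fishmonger, 238 restaurant, 238 supermarket)
_OUTLET_MIX = {"fishmonger": 196 / 672, "restaurant": 238 / 672, "supermarket": 238 / 672}

#: overall specificity mix: 25.5% species, 18.8% genus, 17.6% family,
#: 38.2% higher (reported label-quality distribution); reused per group by
#: default but overridable per group.
_SPECIFICITY_MIX = {4: 0.255, 3: 0.188, 2: 0.176, 1: 0.381}

#: default substitution probability per group, applied at every specificity
#: level (observed group mislabelling rates: sharks/rays and snapper high,
#: hoki/prawns low)
_MISLABEL_PROB = {
    "hoki": 0.010,
    "prawns": 0.020,
    "sharks and rays": 0.359,
    "snapper": 0.252,
    "squid and cuttlefish": 0.126,
    "tuna": 0.042,
}


class ConfigurationError(ValueError):
    """Invalid or infeasible study design."""


def cumulative_true_mislabel_prob(
    species_level_rate, groups: tuple[str, ...] = GROUPS
) -> dict:
    """Cell probabilities consistent with a latent coarsening mechanism.

    Under the censored-survival view, each product has a latent finest
    level T at which its label first mismatches; a product labelled at
    level l is mislabelled iff T <= l, so the cell probability must be the
    cumulative incidence P(T <= l), increasing with l and reaching the
    species-level rate at l = 4.  A constant discrete hazard h per level
    gives ``p_l = 1 - (1 - h)**l`` with ``(1-h)**4 = 1 - rate``.  Because
    every product is observed only at its own label's level, drawing its
    event from p_l is exactly equivalent to drawing the latent T.

    ``species_level_rate`` may be a single float or a per-group dict.
    """
    if not isinstance(species_level_rate, dict):
        species_level_rate = {g: float(species_level_rate) for g in groups}
    out = {}
    for g in groups:
        r = species_level_rate[g]
        if not 0 <= r < 1:
            raise ConfigurationError(f"species-level rate for {g!r} must be in [0,1)")
        surv = (1.0 - r) ** 0.25  # per-level event-free probability
        for lvl in (1, 2, 3, 4):
            out[(g, lvl)] = 1.0 - surv**lvl
    return out


def _norm_mix(d: dict, what: str) -> dict:
    tot = float(sum(d.values()))
    if abs(tot - 1.0) > 1e-12:
        raise ConfigurationError(f"{what} probabilities sum to {tot}, not 1")
    return d


@dataclass
class StudyDesign:
    """Design of a synthetic market survey.

    Defaults reproduce the study conditions the generator emulates:
    7 states x 96 samples, six groups, 50:50 origin split, prices
    log-uniform on [3.43, 299.90] $/kg with 5.5% missing completely at
    random.
    """

    n_states: int = 7
    samples_per_state: int = 96
    groups: tuple[str, ...] = GROUPS
    group_mix: dict = field(default_factory=lambda: dict(_GROUP_MIX))
    outlet_mix: dict = field(default_factory=lambda: dict(_OUTLET_MIX))
    origin_split: float = 0.5
    specificity_mix_per_group: dict = field(
        default_factory=lambda: {g: dict(_SPECIFICITY_MIX) for g in GROUPS}
    )
    true_mislabel_prob: dict = field(
        default_factory=lambda: {
            (g, lvl): _MISLABEL_PROB[g] for g in GROUPS for lvl in (1, 2, 3, 4)
        }
    )
    price_range: tuple[float, float] = (3.43, 299.90)
    missing_price_frac: float = 0.055
    scientific_name_frac: float = 0.3
    vendor_claim_frac: float = 0.25
    certified_frac: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_states <= 0 or self.samples_per_state <= 0:
            raise ConfigurationError("n_states and samples_per_state must be positive")
        if self.price_range[0] <= 0 or self.price_range[0] >= self.price_range[1]:
            raise ConfigurationError("price_range must be a positive interval")
        if not 0 <= self.missing_price_frac <= 1:
            raise ConfigurationError("missing_price_frac must be in [0,1]")
        if not 0 <= self.origin_split <= 1:
            raise ConfigurationError("origin_split must be in [0,1]")
        _norm_mix(self.group_mix, "group_mix")
        _norm_mix(self.outlet_mix, "outlet_mix")
        for g in self.groups:
            if g not in self.specificity_mix_per_group:
                raise ConfigurationError(f"no specificity mix for group {g!r}")
            _norm_mix(self.specificity_mix_per_group[g], f"specificity mix[{g!r}]")
        for g in self.groups:
            for lvl in (1, 2, 3, 4):
                p = self.true_mislabel_prob.get((g, lvl))
                if p is None or not 0 <= p <= 1:
                    raise ConfigurationError(
                        f"true_mislabel_prob missing/invalid for ({g!r}, level {lvl})"
                    )

    @property
    def n_total(self) -> int:
        return self.n_states * self.samples_per_state


# --------------------------------------------------------------------------
# demo reference tables (small, synthetic stand-in for the study's curated
# label-to-species table; far fewer species than the real supplementary
# table, but the same structure and the same contested terms)
# --------------------------------------------------------------------------

# species, genus, family, tags, synonyms
_TAXA = [
    # hoki & whitefish
    ("Macruronus novaezelandiae", "Macruronus", "Merlucciidae", "", ""),
    ("Macruronus magellanicus", "Macruronus", "Merlucciidae", "", ""),
    ("Merluccius australis", "Merluccius", "Merlucciidae", "", ""),
    ("Genypterus blacodes", "Genypterus", "Ophidiidae", "", ""),
    # prawns
    ("Penaeus plebejus", "Penaeus", "Penaeidae", "", "Melicertus plebejus"),
    ("Penaeus monodon", "Penaeus", "Penaeidae", "", ""),
    ("Penaeus esculentus", "Penaeus", "Penaeidae", "", ""),
    ("Penaeus vannamei", "Penaeus", "Penaeidae", "", "Litopenaeus vannamei"),
    ("Metapenaeus endeavouri", "Metapenaeus", "Penaeidae", "", ""),
    ("Pandalus borealis", "Pandalus", "Pandalidae", "", ""),
    # sharks (selachimorphs)
    ("Mustelus antarcticus", "Mustelus", "Triakidae", "selachimorph", ""),
    ("Mustelus lenticulatus", "Mustelus", "Triakidae", "selachimorph", ""),
    ("Galeorhinus galeus", "Galeorhinus", "Triakidae", "selachimorph", ""),
    ("Carcharhinus plumbeus", "Carcharhinus", "Carcharhinidae", "selachimorph", ""),
    ("Carcharhinus amboinensis", "Carcharhinus", "Carcharhinidae", "selachimorph", ""),
    ("Carcharhinus obscurus", "Carcharhinus", "Carcharhinidae", "selachimorph", ""),
    ("Sphyrna zygaena", "Sphyrna", "Sphyrnidae", "selachimorph", ""),
    ("Notorynchus cepedianus", "Notorynchus", "Hexanchidae", "selachimorph", ""),
    # chimaeras (holocephalans) and rays
    ("Callorhinchus milii", "Callorhinchus", "Callorhinchidae", "holocephalan", ""),
    ("Callorhinchus capensis", "Callorhinchus", "Callorhinchidae", "holocephalan", ""),
    ("Atlantoraja castelnaui", "Atlantoraja", "Arhynchobatidae", "batoid", ""),
    ("Dasyatis brevicaudata", "Dasyatis", "Dasyatidae", "batoid", "Bathytoshia brevicaudata"),
    # snappers and look-alikes
    ("Lutjanus malabaricus", "Lutjanus", "Lutjanidae", "", ""),
    ("Lutjanus erythropterus", "Lutjanus", "Lutjanidae", "", ""),
    ("Chrysophrys auratus", "Chrysophrys", "Sparidae", "", "Pagrus auratus"),
    ("Rhabdosargus sarba", "Rhabdosargus", "Sparidae", "", ""),
    ("Centroberyx affinis", "Centroberyx", "Berycidae", "", ""),
    ("Lethrinus nebulosus", "Lethrinus", "Lethrinidae", "", ""),
    ("Nemadactylus macropterus", "Nemadactylus", "Cheilodactylidae", "", ""),
    ("Oreochromis niloticus", "Oreochromis", "Cichlidae", "", ""),
    ("Lates calcarifer", "Lates", "Latidae", "", ""),
    ("Protonibea diacanthus", "Protonibea", "Sciaenidae", "", ""),
    # squid and cuttlefish
    ("Nototodarus gouldi", "Nototodarus", "Ommastrephidae", "", ""),
    ("Sepioteuthis australis", "Sepioteuthis", "Loliginidae", "", ""),
    ("Sepioteuthis lessoniana", "Sepioteuthis", "Loliginidae", "", ""),
    ("Sepia apama", "Sepia", "Sepiidae", "", ""),
    ("Sepia officinalis", "Sepia", "Sepiidae", "", ""),
    ("Metasepia pfefferi", "Metasepia", "Sepiidae", "", ""),
    # tunas and substitutes
    ("Thunnus thynnus", "Thunnus", "Scombridae", "", ""),
    ("Thunnus maccoyii", "Thunnus", "Scombridae", "", ""),
    ("Thunnus albacares", "Thunnus", "Scombridae", "", ""),
    ("Katsuwonus pelamis", "Katsuwonus", "Scombridae", "", ""),
    ("Salmo salar", "Salmo", "Salmonidae", "", ""),
    ("Gadus chalcogrammus", "Gadus", "Gadidae", "", "Theragra chalcogramma"),
]

_SELACHIMORPHS = [t[0] for t in _TAXA if t[3] == "selachimorph"]
_HOLOCEPHALANS = [t[0] for t in _TAXA if t[3] == "holocephalan"]

# comprehensive-regime terms: term -> (group, permitted species list)
_TERMS = {
    "blue grenadier": ("hoki", ["Macruronus novaezelandiae"]),
    "hoki": ("hoki", ["Macruronus novaezelandiae", "Macruronus magellanicus"]),
    "hake": (
        "hoki",
        ["Macruronus novaezelandiae", "Macruronus magellanicus", "Merluccius australis"],
    ),
    "whitefish": (
        "hoki",
        [
            "Macruronus novaezelandiae",
            "Macruronus magellanicus",
            "Merluccius australis",
            "Genypterus blacodes",
        ],
    ),
    "king prawn": ("prawns", ["Penaeus plebejus"]),
    "vannamei prawn": ("prawns", ["Penaeus vannamei"]),
    "tiger prawn": ("prawns", ["Penaeus monodon", "Penaeus esculentus"]),
    "prawn": (
        "prawns",
        [
            "Penaeus plebejus",
            "Penaeus monodon",
            "Penaeus esculentus",
            "Penaeus vannamei",
            "Metapenaeus endeavouri",
        ],
    ),
    "shrimp": (
        "prawns",
        [
            "Penaeus plebejus",
            "Penaeus monodon",
            "Penaeus esculentus",
            "Penaeus vannamei",
            "Metapenaeus endeavouri",
            "Pandalus borealis",
        ],
    ),
    "school shark": ("sharks and rays", ["Galeorhinus galeus"]),
    "sandbar shark": ("sharks and rays", ["Carcharhinus plumbeus"]),
    "gummy shark": ("sharks and rays", ["Mustelus antarcticus", "Mustelus lenticulatus"]),
    "houndshark": (
        "sharks and rays",
        ["Mustelus antarcticus", "Mustelus lenticulatus", "Galeorhinus galeus"],
    ),
    "whaler shark": (
        "sharks and rays",
        ["Carcharhinus plumbeus", "Carcharhinus amboinensis", "Carcharhinus obscurus"],
    ),
    "flake": ("sharks and rays", list(_SELACHIMORPHS)),
    "shark": ("sharks and rays", list(_SELACHIMORPHS)),
    "stingray": ("sharks and rays", ["Atlantoraja castelnaui", "Dasyatis brevicaudata"]),
    "pink snapper": ("snapper", ["Chrysophrys auratus"]),
    "saddletail snapper": ("snapper", ["Lutjanus malabaricus"]),
    "red snapper": ("snapper", ["Lutjanus malabaricus", "Lutjanus erythropterus"]),
    "sea bream": ("snapper", ["Chrysophrys auratus", "Rhabdosargus sarba"]),
    "snapper": (
        "snapper",
        [
            "Lutjanus malabaricus",
            "Lutjanus erythropterus",
            "Chrysophrys auratus",
            "Rhabdosargus sarba",
            "Centroberyx affinis",
            "Lethrinus nebulosus",
            "Nemadactylus macropterus",
        ],
    ),
    "arrow squid": ("squid and cuttlefish", ["Nototodarus gouldi"]),
    "calamari": (
        "squid and cuttlefish",
        ["Sepioteuthis australis", "Sepioteuthis lessoniana"],
    ),
    "cuttlefish": (
        "squid and cuttlefish",
        ["Sepia apama", "Sepia officinalis", "Metasepia pfefferi"],
    ),
    "squid": (
        "squid and cuttlefish",
        ["Nototodarus gouldi", "Sepioteuthis australis", "Sepioteuthis lessoniana"],
    ),
    "atlantic bluefin tuna": ("tuna", ["Thunnus thynnus"]),
    "skipjack tuna": ("tuna", ["Katsuwonus pelamis"]),
    "bluefin tuna": ("tuna", ["Thunnus thynnus", "Thunnus maccoyii"]),
    "tuna": (
        "tuna",
        ["Thunnus thynnus", "Thunnus maccoyii", "Thunnus albacares", "Katsuwonus pelamis"],
    ),
    "oily fish": (
        "tuna",
        [
            "Thunnus thynnus",
            "Thunnus maccoyii",
            "Thunnus albacares",
            "Katsuwonus pelamis",
            "Salmo salar",
        ],
    ),
    # substitution species' own market names (never drawn as survey labels;
    # keep every taxonomy species reachable from some term)
    "tilapia": ("other", ["Oreochromis niloticus"]),
    "barramundi": ("other", ["Lates calcarifer"]),
    "black jewfish": ("other", ["Protonibea diacanthus"]),
    "alaska pollock": ("other", ["Gadus chalcogrammus"]),
}

# AFNS-regime overrides: stricter sets for contested umbrella terms
_AFNS_OVERRIDES = {
    "flake": ["Mustelus antarcticus", "Mustelus lenticulatus"],
    "snapper": [
        "Lutjanus malabaricus",
        "Lutjanus erythropterus",
        "Chrysophrys auratus",
        "Rhabdosargus sarba",
    ],
    "shrimp": [
        "Penaeus plebejus",
        "Penaeus monodon",
        "Penaeus esculentus",
        "Penaeus vannamei",
    ],
    "calamari": ["Sepioteuthis australis"],
    "squid": ["Nototodarus gouldi"],
}

#: approved standard names (demo AFNS list); deliberately excludes the
#: contested/vague terms "calamari", "shark", "stingray", "red snapper"
#: and "pink snapper"
_AFNS_NAMES = [
    "whitefish",
    "shrimp",
    "oily fish",
    "houndshark",
    "blue grenadier",
    "hoki",
    "hake",
    "king prawn",
    "vannamei prawn",
    "tiger prawn",
    "prawn",
    "school shark",
    "sandbar shark",
    "gummy shark",
    "whaler shark",
    "flake",
    "saddletail snapper",
    "sea bream",
    "snapper",
    "arrow squid",
    "southern calamari",
    "cuttlefish",
    "squid",
    "atlantic bluefin tuna",
    "skipjack tuna",
    "bluefin tuna",
    "tuna",
]

#: out-of-group (or off-label) substitution pools, qualitatively mirroring
#: the observed substitution patterns: chimaeras sold as flake, tilapia and
#: barramundi as snapper, Alaska pollock as tuna
DEFAULT_CONFUSION = {
    "hoki": ["Genypterus blacodes", "Merluccius australis", "Oreochromis niloticus"],
    "prawns": ["Penaeus vannamei", "Pandalus borealis", "Oreochromis niloticus"],
    "sharks and rays": _HOLOCEPHALANS + ["Atlantoraja castelnaui"],
    "snapper": ["Oreochromis niloticus", "Lates calcarifer", "Protonibea diacanthus"],
    "squid and cuttlefish": ["Sepia apama", "Nototodarus gouldi"],
    "tuna": ["Gadus chalcogrammus", "Thunnus albacares"],
}


def demo_taxonomy() -> pd.DataFrame:
    return pd.DataFrame(
        _TAXA, columns=["species", "genus", "family", "tags", "synonyms"]
    )


def demo_label_table() -> pd.DataFrame:
    """Long-format (term, regime, species) table for the four regimes.

    ``strict_flake`` and ``lenient_flake`` are identical to ``comprehensive``
    except on the term "flake"; ``afns`` tightens several umbrella terms.
    """
    rows = []
    for term, (_, species) in _TERMS.items():
        for sp in species:
            rows.append((term, "comprehensive", sp))
        for sp in _AFNS_OVERRIDES.get(term, species):
            rows.append((term, "afns", sp))
        strict = (
            ["Mustelus antarcticus", "Mustelus lenticulatus"]
            if term == "flake"
            else species
        )
        for sp in strict:
            rows.append((term, "strict_flake", sp))
        lenient = species + _HOLOCEPHALANS if term == "flake" else species
        for sp in lenient:
            rows.append((term, "lenient_flake", sp))
    return pd.DataFrame(rows, columns=["term", "regime", "species"])


def demo_afns_list() -> pd.DataFrame:
    return pd.DataFrame({"name": _AFNS_NAMES})


def demo_reference() -> LabelReference:
    """LabelReference built from the packaged demo tables."""
    return LabelReference(demo_label_table(), demo_taxonomy())


def _group_terms_by_level(ref: LabelReference) -> dict[tuple[str, int], list[str]]:
    """(group, level) -> candidate comprehensive-regime terms."""
    out: dict[tuple[str, int], list[str]] = {}
    for term, (group, _) in _TERMS.items():
        lvl = ref.label_specificity(term, "comprehensive")
        out.setdefault((group, lvl), []).append(term)
    for lst in out.values():
        lst.sort()
    return out


def _largest_remainder(total: int, probs: dict) -> dict:
    """Integer allocation of `total` over categories; ties lexicographic."""
    keys = sorted(probs, key=str)
    raw = {k: total * float(probs[k]) for k in keys}
    base = {k: int(np.floor(raw[k])) for k in keys}
    short = total - sum(base.values())
    order = sorted(keys, key=lambda k: (-(raw[k] - base[k]), str(k)))
    for k in order[:short]:
        base[k] += 1
    return base


# --------------------------------------------------------------------------
# products
# --------------------------------------------------------------------------


def generate_products(
    design: StudyDesign,
    reference: LabelReference | None = None,
    confusion: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the product metadata table and its ground truth.

    Returns ``(products, truth)``.  ``products`` has one row per purchased
    item with label strings, stratification covariates and price;
    ``truth`` records the species actually in the packet and whether it was
    substituted relative to the label's comprehensive-regime permitted set.

    Deterministic given ``design.seed``.  State, group, origin, outlet and
    specificity counts follow the design exactly via largest-remainder
    allocation; raises :class:`ConfigurationError` if a group is assigned
    positive probability at a specificity level with no label term.
    """
    design.validate()
    ref = reference if reference is not None else demo_reference()
    confusion = confusion if confusion is not None else DEFAULT_CONFUSION
    rng = np.random.default_rng(design.seed)
    terms_by = _group_terms_by_level(ref)

    for g in design.groups:
        for lvl, p in design.specificity_mix_per_group[g].items():
            if p > 0 and not terms_by.get((g, int(lvl))):
                raise ConfigurationError(
                    f"group {g!r} requests specificity level {lvl} but the label "
                    "table has no term for that cell"
                )

    states = [
        STATES[i] if design.n_states == 7 else f"STATE{i+1}"
        for i in range(design.n_states)
    ]
    group_acc = {
        g: {ref.accepted_name(s) for s in _group_species(g)} - {None}
        for g in design.groups
    }
    prows, trows = [], []
    sid = 0
    for state in states:
        n = design.samples_per_state
        g_counts = _largest_remainder(n, design.group_mix)
        o_counts = _largest_remainder(n, design.outlet_mix)
        d_count = _largest_remainder(
            n, {"domestic": design.origin_split, "imported": 1 - design.origin_split}
        )
        outlets = [o for o, c in sorted(o_counts.items()) for _ in range(c)]
        origins = [o for o, c in sorted(d_count.items()) for _ in range(c)]
        rng.shuffle(outlets)
        rng.shuffle(origins)
        i_in_state = 0
        for group in sorted(g_counts, key=str):
            n_g = g_counts[group]
            if n_g == 0:
                continue
            lvl_counts = _largest_remainder(
                n_g, design.specificity_mix_per_group[group]
            )
            levels = [int(l) for l, c in sorted(lvl_counts.items()) for _ in range(c)]
            rng.shuffle(levels)
            for lvl in levels:
                sid += 1
                sample_id = f"S{sid:04d}"
                outlet = outlets[i_in_state]
                origin = origins[i_in_state]
                i_in_state += 1

                term = str(rng.choice(terms_by[(group, lvl)]))
                permitted = ref.resolve(term, "comprehensive").species
                group_species = sorted(permitted & group_acc[group]) or sorted(
                    permitted
                )

                p_sub = design.true_mislabel_prob[(group, lvl)]
                pool = sorted(
                    {ref.accepted_name(s) for s in confusion.get(group, [])}
                    - set(permitted)
                    - {None}
                )
                substituted = bool(pool) and (rng.random() < p_sub)
                if substituted:
                    true_species = str(rng.choice(pool))
                    source = (
                        "within_group"
                        if true_species in group_acc[group]
                        else "out_of_group"
                    )
                else:
                    true_species = str(rng.choice(group_species))
                    source = ""

                # label strings: display form of the term; species-level
                # labels sometimes carry the scientific name instead
                label_main = term.title()
                if lvl == SPECIFICITY_CODES["species"] and rng.random() < design.scientific_name_frac:
                    labelled_sp = sorted(permitted)[0]
                    label_detail = labelled_sp.capitalize()
                else:
                    label_detail = term
                if rng.random() < 0.15:
                    label_main = label_main + "s"  # plural noise

                vendor_claim = ""
                if rng.random() < design.vendor_claim_frac:
                    if rng.random() < 0.55:
                        vendor_claim = true_species.capitalize()
                    else:
                        vendor_claim = str(rng.choice(sorted(ref.all_species))).capitalize()

                lo, hi = design.price_range
                price = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                if rng.random() < design.missing_price_frac:
                    price = np.nan

                packaged = bool(
                    rng.random() < (0.9 if outlet == "supermarket" else 0.3)
                )
                prows.append(
                    {
                        "sample_id": sample_id,
                        "state": state,
                        "outlet_type": outlet,
                        "seafood_group": group,
                        "origin": origin,
                        "label_main": label_main,
                        "label_max_detail": label_detail,
                        "vendor_claim": vendor_claim,
                        "price_per_kg": round(price, 2) if np.isfinite(price) else np.nan,
                        "wild_or_farmed": "wild" if rng.random() < 0.7 else "farmed",
                        "fresh_or_frozen": "fresh" if rng.random() < 0.5 else "frozen",
                        "packaged": packaged,
                        "certified": bool(rng.random() < design.certified_frac),
                    }
                )
                trows.append(
                    {
                        "sample_id": sample_id,
                        "true_species": true_species,
                        "substituted": substituted,
                        "substitution_source": source,
                    }
                )

    products = pd.DataFrame(prows)
    truth = pd.DataFrame(trows)
    return products, truth


def _group_species(group: str) -> list[str]:
    out = set()
    for term, (g, sps) in _TERMS.items():
        if g == group:
            out |= set(sps)
    return sorted(out)


# --------------------------------------------------------------------------
# toy sequence database and Sanger read pairs
# --------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _stable_seed(*parts) -> int:
    h = 0
    for p in parts:
        h = zlib.crc32(str(p).encode(), h)
    return h & 0x7FFFFFFF


def _mutate(seq: np.ndarray, rate: float, rng) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_refdb(
    taxonomy: pd.DataFrame | None = None, length: int = 650, seed: int = 0
) -> dict[str, str]:
    """Toy COI-like reference database: one sequence per species.

    Sequences are hierarchical — a family base sequence mutated ~8% per
    genus and a further ~3% per species — so congeneric species sit near
    (but below) typical barcode identity thresholds, exercising the hit
    filters realistically.  Deterministic in ``seed``.
    """
    tax = taxonomy if taxonomy is not None else demo_taxonomy()
    db: dict[str, str] = {}
    fam_seqs: dict[str, np.ndarray] = {}
    gen_seqs: dict[str, np.ndarray] = {}
    for row in tax.itertuples(index=False):
        fam, gen, sp = row.family, row.genus, row.species
        if fam not in fam_seqs:
            r = np.random.default_rng(_stable_seed(seed, "fam", fam))
            fam_seqs[fam] = r.choice(_BASES, size=length)
        if gen not in gen_seqs:
            r = np.random.default_rng(_stable_seed(seed, "gen", gen))
            gen_seqs[gen] = _mutate(fam_seqs[fam], 0.08, r)
        r = np.random.default_rng(_stable_seed(seed, "sp", sp))
        db[sp.lower()] = _mutate(gen_seqs[gen], 0.03, r).tobytes().decode()
    return db


def generate_reads(
    truth: pd.DataFrame,
    refdb: dict[str, str],
    error_rate: float = 0.0,
    seed: int = 0,
    read_len: int = 300,
    amplicon_len: int = 350,
    dropout_frac: float = 0.0,
) -> dict[str, dict]:
    """Simulate a forward/reverse Sanger pair per sample.

    Both reads come from a single amplicon window at the 5' end of the
    reference barcode (default 350 bases, COI-fragment scale): the forward
    read covers its start, the reverse read is the reverse complement of an
    overlapping window at its end, so the pair still overlaps after
    quality trimming.
    Base qualities are Phred-like integers in [2, 40]; with a nonzero
    ``error_rate`` each base's quality is set near ``-10*log10(rate)`` and
    miscalls are drawn at probability ``10**(-Q/10)``, so quality scores
    mean what they claim.  ``error_rate == 0`` yields error-free reads.

    Returns ``{sample_id: {"forward_seq", "forward_qual", "reverse_seq",
    "reverse_qual"}}``; samples hit by ``dropout_frac`` map to ``None``
    (failed amplification).  Raises ``KeyError`` if a species lacks a
    reference sequence.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    out: dict[str, dict | None] = {}
    for row in truth.itertuples(index=False):
        sp = str(row.true_species).lower()
        if sp not in refdb:
            raise KeyError(f"species {row.true_species!r} absent from reference db")
        ref = refdb[sp]
        if len(ref) < 300:
            raise ValueError(f"reference for {sp!r} shorter than 300 bases")
        rng = np.random.default_rng(_stable_seed(seed, "read", row.sample_id))
        if dropout_frac > 0 and rng.random() < dropout_frac:
            out[row.sample_id] = None
            continue
        amplicon = ref[: min(amplicon_len, len(ref))]
        L = min(read_len, len(amplicon))
        fwd_region = amplicon[:L]
        rev_region = amplicon[len(amplicon) - L :]

        def call(region: str) -> tuple[str, list[int]]:
            arr = np.frombuffer(region.encode(), dtype="S1").copy()
            if error_rate > 0:
                q_base = int(round(-10 * np.log10(error_rate)))
                quals = np.clip(
                    q_base + rng.integers(-3, 4, size=len(arr)), 2, 40
                )
                miscall = rng.random(len(arr)) < 10.0 ** (-quals / 10.0)
                for i in np.flatnonzero(miscall):
                    choices = _BASES[_BASES != arr[i]]
                    arr[i] = rng.choice(choices)
            else:
                quals = rng.integers(35, 41, size=len(arr))
            return arr.tobytes().decode(), [int(q) for q in quals]

        fseq, fqual = call(fwd_region)
        rseq_fwd, rqual_fwd = call(rev_region)
        rseq = rseq_fwd.translate(comp)[::-1]
        rqual = rqual_fwd[::-1]
        out[row.sample_id] = {
            "forward_seq": fseq,
            "forward_qual": fqual,
            "reverse_seq": rseq,
            "reverse_qual": rqual,
        }
    return out


def write_fastq(reads: dict[str, dict | None], fwd_path, rev_path) -> None:
    """Write paired reads as Phred+33 FASTQ (samples with no reads skipped)."""
    with open(fwd_path, "w") as f, open(rev_path, "w") as r:
        for sid in sorted(reads):
            pair = reads[sid]
            if pair is None:
                continue
            for fh, s, q in (
                (f, pair["forward_seq"], pair["forward_qual"]),
                (r, pair["reverse_seq"], pair["reverse_qual"]),
            ):
                fh.write(f"@{sid}\n{s}\n+\n")
                fh.write("".join(chr(33 + int(x)) for x in q) + "\n")


# --------------------------------------------------------------------------
# hit tables
# --------------------------------------------------------------------------


def default_db_entry_counts(refdb: dict[str, str], seed: int = 0) -> dict[str, int]:
    """Synthetic per-species database entry counts.

    Most species get 2-80 entries; a deterministic ~10% subset gets a single
    entry, exercising the single-entry confidence filter downstream.
    """
    counts = {}
    for sp in sorted(refdb):
        rng = np.random.default_rng(_stable_seed(seed, "entries", sp))
        counts[sp] = 1 if rng.random() < 0.1 else int(rng.integers(2, 81))
    return counts


def generate_hit_table(
    qseqid: str,
    consensus: str,
    refdb: dict[str, str],
    db_entry_counts: dict[str, int],
    identity_floor: float = 80.0,
    seed: int = 0,
) -> pd.DataFrame:
    """BLAST-outfmt-6-like hit rows for one consensus sequence.

    Each reference species whose infix edit-distance identity to the
    consensus clears ``identity_floor`` contributes rows — one per matching
    database entry (entries of the same species differ by tiny identity
    jitter), tagged alternately NCBI/BOLD.  The e-value is a monotone proxy
    of identity, not a BLAST statistic.  Empty consensus raises ValueError;
    an empty table (nothing matched) is a valid result.
    """
    if not consensus:
        raise ValueError("empty consensus sequence")
    rows = []
    for sp in sorted(refdb):
        ref = refdb[sp]
        aln = edlib.align(consensus, ref, mode="HW", task="locations")
        dist = aln["editDistance"]
        identity = 100.0 * (1.0 - dist / len(consensus))
        if identity < identity_floor:
            continue
        loc = aln["locations"][0] if aln["locations"] else (0, len(ref) - 1)
        span = loc[1] - loc[0] + 1
        coverage = min(100.0, 100.0 * span / len(consensus))
        entries = int(db_entry_counts.get(sp, 1))
        rng = np.random.default_rng(_stable_seed(seed, "hits", qseqid, sp))
        # fraction of this species' database entries the query actually hits
        n_hits = max(1, int(round(entries * float(rng.uniform(0.5, 0.95)))))
        for j in range(n_hits):
            # best entry reflects the true identity; the rest jitter below it
            ident_j = (
                identity
                if j == 0
                else max(identity_floor, identity - float(rng.uniform(0, 0.4)))
            )
            rows.append(
                {
                    "qseqid": qseqid,
                    "species": sp,
                    "db": "NCBI" if j % 2 == 0 else "BOLD",
                    "identity": round(ident_j, 2),
                    "coverage": round(coverage, 2),
                    "evalue": 10.0 ** (3.0 - 0.35 * ident_j),
                    "species_db_entries": entries,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "qseqid",
            "species",
            "db",
            "identity",
            "coverage",
            "evalue",
            "species_db_entries",
        ],
    )


def generate_hit_tables(
    consensi: dict[str, str],
    refdb: dict[str, str],
    db_entry_counts: dict[str, int] | None = None,
    identity_floor: float = 80.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Concatenated hit table for many consensus sequences."""
    counts = (
        db_entry_counts
        if db_entry_counts is not None
        else default_db_entry_counts(refdb, seed)
    )
    tables = [
        generate_hit_table(sid, seq, refdb, counts, identity_floor, seed)
        for sid, seq in sorted(consensi.items())
        if seq
    ]
    if not tables:
        return generate_hit_table("_", "N", refdb, counts, 101.0, seed).iloc[:0]
    return pd.concat(tables, ignore_index=True)
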
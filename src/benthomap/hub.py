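"""HELCOM HUB code grammar, dominance rules and labelling conventions.

A HUB code bundles the light zone (``AA`` photic / ``AB`` aphotic), a
substrate letter, and the community levels 4-6, e.g. ``AA.J3L9``.  Codes
may carry a trailing uncertainty marker (``AA.I1E1?``), an unknown
substrate (``AA.?3L9``), or be a union of two codes (``AA.G+AA.J1E1``).

Ground-truth stations are labelled by dominance: endobenthic taxa by a
strict >50 % biomass share, epibenthic taxa by >=10 % cover on the total
area or >=90 % cover on the hard substrate.  Before modelling, a set of
harmonisation conventions removes rare/unpredictable dominants and
merges poorly separable communities.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .sediment import EunisSubstrate

__all__ = [
    "HubCode",
    "HubPart",
    "parse_hub",
    "compose_hub",
    "DominanceConfig",
    "ConventionConfig",
    "dominant_endobenthos",
    "dominant_epibenthos",
    "acfor_to_cover",
    "apply_conventions",
    "SUBSTRATE_TO_LETTER",
    "LETTER_TO_SUBSTRATE",
    "HUB_VOCABULARY",
    "ACFOR_COVER",
]

log = logging.getLogger(__name__)

SUBSTRATE_TO_LETTER = {
    EunisSubstrate.MUD: "H",
    EunisSubstrate.COARSE_SEDIMENT: "I",
    EunisSubstrate.SAND: "J",
    EunisSubstrate.MIXED_SEDIMENT_HARD: "M",
    "peat": "G",
    "unknown": "?",
}
LETTER_TO_SUBSTRATE = {
    "H": "mud",
    "I": "coarse_sediment",
    "J": "sand",
    "M": "mixed_sediment_hard",
    "G": "peat",
    "?": "unknown",
}

_LEVEL56_TOKENS = {
    "E1", "C1", "C2", "C3", "C4", "C5", "S1", "S", "G1", "H2", "I1",
    "V", "T", "U", "B7", "L1", "L3", "L4", "L9", "L10", "L11", "M6",
}

_PART_RE = re.compile(
    r"^(?P<zone>AA|AB)\.(?P<substrate>[HIJMG?])"
    r"(?:(?P<level4>[1-4])(?P<level56>[A-Z][0-9]{0,2})?)?"
    r"(?P<uncertain>\?)?$"
)


@dataclass(frozen=True)
class HubPart:
    """One zone.substrate[level4][level5_6][?] segment of a HUB code."""

    zone: str  # "AA" photic, "AB" aphotic
    substrate: str  # H, I, J, M, G, ?
    level4: str | None = None  # "1".."4"
    level56: str | None = None
    uncertain: bool = False

    def __post_init__(self):
        if self.zone not in ("AA", "AB"):
            raise ValueError(f"zone must be AA or AB, got {self.zone!r}")
        if self.substrate not in LETTER_TO_SUBSTRATE:
            raise ValueError(f"unknown substrate letter {self.substrate!r}")
        if self.level4 is not None and self.level4 not in "1234":
            raise ValueError(f"level 4 must be 1-4, got {self.level4!r}")
        if self.level56 is not None:
            if self.level4 is None:
                raise ValueError("level 5/6 token requires a level 4 digit")
            if self.level56 not in _LEVEL56_TOKENS:
                raise ValueError(f"unknown level 5/6 token {self.level56!r}")
            if self.level56 == "T" and self.level4 != "2":
                raise ValueError("token 'T' is only valid under level 4 '2'")
            if self.level56 == "U" and self.level4 != "4":
                raise ValueError("token 'U' is only valid under level 4 '4'")

    @property
    def community(self) -> str:
        """Levels 4-6 as a bare token, e.g. '3L9', '1E1', '' when absent."""
        return (self.level4 or "") + (self.level56 or "")

    def __str__(self) -> str:
        return (
            f"{self.zone}.{self.substrate}{self.community}"
            + ("?" if self.uncertain else "")
        )


@dataclass(frozen=True)
class HubCode:
    """A full HUB code: one part, or a '+' union of two."""

    parts: tuple[HubPart, ...]

    def __post_init__(self):
        if not 1 <= len(self.parts) <= 2:
            raise ValueError("a HUB code has one part or a union of two")

    def __str__(self) -> str:
        return "+".join(str(p) for p in self.parts)


def _parse_part(text: str) -> HubPart:
    m = _PART_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse HUB code segment {text!r}")
    return HubPart(
        zone=m["zone"],
        substrate=m["substrate"],
        level4=m["level4"],
        level56=m["level56"],
        uncertain=m["uncertain"] is not None,
    )


def parse_hub(code: str) -> HubCode:
    """Parse a HUB code string, including '+' unions."""
    segments = code.strip().split("+")
    if not 1 <= len(segments) <= 2:
        raise ValueError(f"HUB code {code!r} has too many union segments")
    return HubCode(parts=tuple(_parse_part(s) for s in segments))


def compose_hub(
    photic: bool,
    substrate: EunisSubstrate | str,
    community: str | None = None,
    uncertain: bool = False,
) -> str:
    """Build a HUB code string from zone, substrate and a community token.

    ``community`` is the levels 4-6 token, e.g. ``"3L9"`` or ``"1E1"``;
    ``None`` or ``""`` stops the code at the substrate level.
    """
    if substrate == EunisSubstrate.ROCK_BIOGENIC_REEF:
        raise ValueError(
            "rock/biogenic reef has no plain HUB substrate letter; only peat "
            "bottoms with mussel cover enter as a peat+sand union code"
        )
    letter = SUBSTRATE_TO_LETTER.get(substrate)
    if letter is None:
        letter = SUBSTRATE_TO_LETTER.get(EunisSubstrate(substrate))
    zone = "AA" if photic else "AB"
    community = community or ""
    part = HubPart(
        zone=zone,
        substrate=letter,
        level4=community[:1] or None,
        level56=community[1:] or None,
        uncertain=uncertain,
    )
    return str(part)


#: Every HUB code realised on the mapped-biotope legend; used for
#: round-trip grammar checks and as the closed label vocabulary.
HUB_VOCABULARY = [
    "AA.?", "AB.?", "AA.?1E1", "AA.?3", "AA.?3L3", "AB.?3L3", "AA.?3L4",
    "AA.?3L9", "AA.M", "AB.M", "AA.M1", "AB.M1", "AA.M1C1", "AA.M1C2",
    "AA.M1C3", "AB.M1C3", "AA.M1C5", "AA.M1E1", "AA.M1E1?", "AB.M1E1",
    "AA.M1G1", "AB.M1G1", "AA.M1H2", "AB.M1I1", "AA.M1S1", "AA.M1V",
    "AB.M1V", "AA.M2T", "AB.M2T", "AB.M4U", "AA.G+AA.J1E1", "AA.I",
    "AA.I1E1", "AA.I1E1?", "AB.I1E1", "AA.I1C3", "AA.I3", "AB.I3",
    "AA.I3L3", "AB.I3L3", "AA.I3L4", "AA.I3L9", "AB.I3L9", "AA.I3L10",
    "AB.I3L10", "AA.I3L11", "AB.I3M6", "AA.J", "AB.J", "AA.J1B7",
    "AA.J1E1", "AB.J1E1", "AA.J1S", "AA.J3", "AB.J3", "AA.J3L1",
    "AB.J3L1", "AA.J3L3", "AB.J3L3", "AA.J3L4", "AB.J3L4", "AA.J3L9",
    "AB.J3L9", "AA.J3L10", "AB.J3L10", "AA.J3L11", "AA.J3M6", "AB.J3M6",
    "AA.H1B7", "AA.H1E1", "AB.H1E1", "AA.H1S", "AA.H3", "AB.H3",
    "AB.H3L1", "AA.H3L3", "AB.H3L3", "AA.H3L4", "AB.H3L4", "AA.H3L9",
    "AB.H3L9", "AA.H3L10", "AB.H3L10", "AB.H3M6",
]


# ---------------------------------------------------------------------------
# Dominance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DominanceConfig:
    """Fixed dominance thresholds (percent)."""

    endo_biomass_pct: float = 50.0  # strict >
    epi_total_cover_pct: float = 10.0  # inclusive >=
    epi_hard_cover_pct: float = 90.0  # inclusive >=


def dominant_endobenthos(
    biomass: dict[str, float], config: DominanceConfig = DominanceConfig()
) -> str | None:
    """Taxon holding strictly more than half the biomass, else None.

    A zero total signals an empty sample (no-macrocommunity candidate).
    """
    if any(v < 0 for v in biomass.values()):
        raise ValueError("biomass values must be non-negative")
    total = sum(biomass.values())
    if total <= 0:
        return None
    for taxon, grams in biomass.items():
        if 100.0 * grams / total > config.endo_biomass_pct:
            return taxon
    return None


def dominant_epibenthos(
    cover: dict[str, float],
    hard_cover_pct: float,
    config: DominanceConfig = DominanceConfig(),
    precedence: tuple[str, ...] = (),
) -> str | None:
    """Dominant epibenthic taxon by cover.

    A taxon qualifies at >=10 % cover of the total area, or when its
    cover rescaled to the hard-substrate area reaches >=90 %.  The
    largest total cover among qualifiers wins; exact ties fall to the
    precedence list (structuring, long-lived taxa first).
    """
    for taxon, pct in cover.items():
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"cover of {taxon!r} outside [0, 100]: {pct}")
    if not 0.0 <= hard_cover_pct <= 100.0:
        raise ValueError("hard_cover_pct outside [0, 100]")

    qualifiers = []
    for taxon, pct in cover.items():
        ok = pct >= config.epi_total_cover_pct
        if not ok:
            if hard_cover_pct > 0:
                on_hard = 100.0 * pct / hard_cover_pct
                ok = on_hard >= config.epi_hard_cover_pct
            else:
                log.info("hard-substrate criterion skipped: no hard cover in view")
        if ok:
            qualifiers.append((taxon, pct))
    if not qualifiers:
        return None
    best = max(pct for _, pct in qualifiers)
    tied = [t for t, pct in qualifiers if pct == best]
    if len(tied) == 1:
        return tied[0]
    for preferred in precedence:
        if preferred in tied:
            return preferred
    return sorted(tied)[0]


#: Midpoint cover percentages of the semi-quantitative ACFOR scale.
ACFOR_COVER = {"A": 75.0, "C": 35.0, "F": 15.0, "O": 5.0, "R": 1.0}


def acfor_to_cover(acfor: str) -> float:
    """Map an ACFOR letter to a representative percent cover."""
    try:
        return ACFOR_COVER[acfor.strip().upper()]
    except KeyError:
        raise KeyError(
            f"unknown ACFOR letter {acfor!r}; valid letters: A, C, F, O, R"
        ) from None


# ---------------------------------------------------------------------------
# Harmonisation conventions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConventionConfig:
    """Knobs of the pre-modelling label harmonisation.

    ``merge_map`` rewrites community tokens of poorly separable
    dominants; ``rare_taxa``/``deleted_taxa`` name dominants whose
    stations are removed (the former only when they account for at most
    ``rare_taxon_station_pct`` percent of all stations).
    """

    rare_taxon_station_pct: float = 1.0
    rare_taxa: tuple[str, ...] = ("Actiniaria", "Oligochaeta")
    deleted_taxa: tuple[str, ...] = ("Ophelia", "Travisia")
    merge_map: dict = field(
        default_factory=lambda: {
            # sand gaper and Astarte into the multi-bivalve community
            "3L4": "3L9",
            "3L10": "3L9",
            # named polychaete communities into bare infaunal structures
            "3M6": "3",
            # endo labels ending at level 5 into bare infaunal structures
            "3L": "3",
            "3M": "3",
        }
    )
    promote_epi_level5: bool = True
    epi_level5_promotion: dict = field(
        default_factory=lambda: {"1C": "1C3", "1S": "1S1", "1G": "1G1", "1E": "1E1"}
    )
    precedence: tuple[str, ...] = (
        "Fucus",
        "perennial non-filamentous corticated red algae",
        "foliose red algae",
        "Mytilidae",
        "perennial filamentous algae",
        "Hydrozoa",
        "filamentous annual algae",
    )

    def __post_init__(self):
        for target in self.merge_map.values():
            if target and target[:1] not in "1234":
                raise ValueError(f"merge target {target!r} is not a HUB token")


def collapse_mixed_community(taxon: str, config: ConventionConfig) -> str:
    """Reduce a slash-joined mixed dominant to its structuring taxon."""
    if "/" not in taxon:
        return taxon
    components = [c.strip() for c in taxon.split("/")]
    for preferred in config.precedence:
        if preferred in components:
            return preferred
    return components[0]


def apply_conventions(
    labels: pd.DataFrame, config: ConventionConfig = ConventionConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonise station labels before modelling.

    ``labels`` needs columns ``station_id``, ``realm`` (endo/epi),
    ``dominant_taxon`` (may be empty) and ``label`` (community token,
    levels 4-6).  Returns ``(kept, excluded)``: the kept frame gains a
    ``harmonized_label`` column, the excluded frame a ``reason`` column.
    The operation is idempotent.
    """
    df = labels.copy()
    n = len(df)
    taxa = df["dominant_taxon"].fillna("")

    # station removals
    drop_reason = pd.Series("", index=df.index)
    for taxon in config.deleted_taxa:
        hit = taxa.str.startswith(taxon) & (drop_reason == "")
        drop_reason[hit] = f"unpredictable dominant ({taxon})"
    if n > 0:
        freq = taxa.map(taxa.value_counts()) / n * 100.0
        for taxon in config.rare_taxa:
            hit = (
                taxa.str.startswith(taxon)
                & (freq <= config.rare_taxon_station_pct)
                & (drop_reason == "")
            )
            drop_reason[hit] = f"rare dominant ({taxon})"

    excluded = df[drop_reason != ""].copy()
    excluded["reason"] = drop_reason[drop_reason != ""]
    kept = df[drop_reason == ""].copy()
    for _, row in excluded.iterrows():
        log.info("station %s excluded: %s", row["station_id"], row["reason"])

    def harmonise(row) -> str:
        token = row["label"] or ""
        token = config.merge_map.get(token, token)
        if (
            row["realm"] == "epi"
            and config.promote_epi_level5
            and token in config.epi_level5_promotion
        ):
            token = config.epi_level5_promotion[token]
        return token

    kept["harmonized_label"] = kept.apply(harmonise, axis=1) if len(kept) else pd.Series(dtype=object)
    return kept, excluded


# ---------------------------------------------------------------------------
# Station labelling
# ---------------------------------------------------------------------------

#: Community token (levels 4-6) named by a dominant endobenthic taxon.
ENDO_TAXON_TOKENS = {
    "Arctica islandica": "3L3",
    "Macoma balthica": "3L1",
    "Cerastoderma glaucum": "3L9",
    "Cerastoderma spp.": "3L9",
    "Mya arenaria": "3L4",
    "Astarte borealis": "3L10",
    "Macoma calcarea": "3L10",
    "Scoloplos armiger": "3M6",
    "Marenzelleria spp.": "3M6",
    "Pygospio elegans": "3M6",
    "Hediste diversicolor": "3M6",
    "Ophelia spp.": "3L11",
    "Travisia forbesii": "3L11",
}

#: Community token named by a dominant epibenthic taxon.
EPI_TAXON_TOKENS = {
    "Mytilidae": "1E1",
    "Mytilus edulis": "1E1",
    "Fucus": "1C1",
    "Fucus spp.": "1C1",
    "perennial non-filamentous corticated red algae": "1C2",
    "foliose red algae": "1C3",
    "perennial filamentous algae": "1C5",
    "filamentous annual algae": "1S1",
    "Hydrozoa": "1G1",
    "Flustra foliacea": "1H2",
    "Balanidae": "1I1",
    "Zostera marina": "1B7",
}


def label_endo_station(
    biomass: dict[str, float], config: DominanceConfig = DominanceConfig()
) -> tuple[str, str | None]:
    """(community token, dominant taxon) of a grab sample.

    No biomass at all means no macrocommunity ('4'); a non-empty sample
    without a >50 % dominant carries macroscopic infaunal structures
    ('3'); a dominant taxon names its level 5/6 community, defaulting to
    '3' for taxa without their own class.
    """
    total = sum(biomass.values())
    if total <= 0:
        return "4", None
    dominant = dominant_endobenthos(biomass, config)
    if dominant is None:
        return "3", None
    return ENDO_TAXON_TOKENS.get(dominant, "3"), dominant


def label_epi_station(
    cover: dict[str, float],
    hard_cover_pct: float,
    config: DominanceConfig = DominanceConfig(),
    convention: ConventionConfig = ConventionConfig(),
) -> tuple[str, str | None]:
    """(community token, dominant taxon) of a video/photo station.

    No cover at all means no macrocommunity ('4U'); cover without a
    qualifying dominant means sparse colonisation ('2T').  Mixed
    (slash-joined) dominants collapse to their structuring taxon first.
    """
    if not cover or all(v <= 0 for v in cover.values()):
        return "4U", None
    dominant = dominant_epibenthos(
        cover, hard_cover_pct, config, precedence=convention.precedence
    )
    if dominant is None:
        return "2T", None
    dominant = collapse_mixed_community(dominant, convention)
    return EPI_TAXON_TOKENS.get(dominant, "1"), dominant


def label_stations(
    stations: pd.DataFrame,
    dominance: DominanceConfig = DominanceConfig(),
    convention: ConventionConfig = ConventionConfig(),
) -> pd.DataFrame:
    """Label every station in a long observation table.

    ``stations`` has one row per station x taxon with columns
    ``station_id``, ``method`` ('grab' or video/photo/diver), ``taxon``,
    ``value`` (grams for grabs, percent cover otherwise) and
    ``hard_cover_pct``.  Returns one row per station with ``realm``,
    ``dominant_taxon`` and ``label``.
    """
    out = []
    for station_id, group in stations.groupby("station_id", sort=True):
        method = group["method"].iloc[0]
        values = dict(zip(group["taxon"], group["value"]))
        if method == "grab":
            token, dominant = label_endo_station(values, dominance)
            realm = "endo"
        else:
            hard_pct = group["hard_cover_pct"].iloc[0]
            hard_pct = 0.0 if pd.isna(hard_pct) else float(hard_pct)
            token, dominant = label_epi_station(values, hard_pct, dominance, convention)
            realm = "epi"
        row = {
            "station_id": station_id,
            "realm": realm,
            "dominant_taxon": dominant,
            "label": token,
        }
        for extra in ("x", "y", "row", "col", "true_label"):
            if extra in group.columns:
                row[extra] = group[extra].iloc[0]
        out.append(row)
    return pd.DataFrame(out)
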
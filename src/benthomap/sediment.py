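"""Grain-size based sediment classification.

Implements three classification levels used on national sediment maps
(Level A broad groups, Level B Folk triangle classes, Level C sand
subdivisions), the EUNIS substrate categories used by broad habitat
types, and the translation of legacy soft-bottom map classes to EUNIS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "GrainSizeComposition",
    "EunisSubstrate",
    "BshClass",
    "EunisThresholds",
    "classify_folk",
    "classify_figge_sand",
    "classify_eunis",
    "classify_full",
    "translate_tauber",
    "TAUBER_TO_EUNIS",
]

log = logging.getLogger(__name__)

_SUM_TOL = 1e-9


class EunisSubstrate(str, Enum):
    """Closed vocabulary of EUNIS broad substrate categories."""

    MUD = "mud"
    SAND = "sand"
    COARSE_SEDIMENT = "coarse_sediment"
    MIXED_SEDIMENT_HARD = "mixed_sediment_hard"
    ROCK_BIOGENIC_REEF = "rock_biogenic_reef"


# Level A groups and the Level B classes each one admits.
LEVEL_A_TO_B = {
    "Fsed": {"M", "sM", "mS", "not specified"},
    "S": {"S", "not specified"},
    "Csed": {"gS", "sG", "G", "not specified"},
    "MxSed": {"gM", "msG", "mG", "not specified"},
    "Peat": {"not classified"},
    "LagSed": {"not classified"},
    "not specified": {"not specified"},
}

LEVEL_C_CLASSES = {"fSa", "mSa", "mxSa", "cSa", "not classified", "not specified"}


@dataclass(frozen=True)
class BshClass:
    """A sediment class expressed at classification levels A, B and C."""

    level_a: str
    level_b: str = "not specified"
    level_c: str = "not classified"

    def __post_init__(self):
        if self.level_a not in LEVEL_A_TO_B:
            raise ValueError(
                f"unknown Level A class {self.level_a!r}; "
                f"expected one of {sorted(LEVEL_A_TO_B)}"
            )
        allowed_b = LEVEL_A_TO_B[self.level_a] | {"not classified"}
        if self.level_b not in allowed_b:
            raise ValueError(
                f"Level B class {self.level_b!r} not permitted under "
                f"Level A {self.level_a!r}"
            )
        if self.level_c not in LEVEL_C_CLASSES:
            raise ValueError(f"unknown Level C class {self.level_c!r}")
        if self.level_c in {"fSa", "mSa", "mxSa", "cSa"} and self.level_a != "S":
            raise ValueError("Level C sand subdivision requires Level A 'S'")


@dataclass(frozen=True)
class EunisThresholds:
    """Fixed percentage thresholds of the EUNIS substrate rules."""

    mud_min_pct: float = 20.0
    gravel_share_min_pct: float = 30.0
    sand_share_min_pct: float = 70.0
    mixed_hard_min_pct: float = 10.0
    mixed_hard_max_pct: float = 90.0
    pure_min_pct: float = 90.0

    def __post_init__(self):
        if not (0.0 < self.mixed_hard_min_pct < self.mixed_hard_max_pct < 100.0):
            raise ValueError("mixed-sediment hard-cover band must satisfy 0 < lo < hi < 100")


@dataclass(frozen=True)
class GrainSizeComposition:
    """Mass fractions of a sediment sample.

    ``mud`` is the <63 µm fraction, ``sand`` 0.063–2 mm and ``gravel``
    >2 mm; the three must sum to 1.  Sand subfractions (``fine``
    0.063–0.25 mm, ``medium`` 0.25–0.5 mm, ``coarse`` 0.5–2 mm) are
    expressed as fractions of the *total* mass and, when given, must sum
    to the sand fraction.  ``hard_cover_pct`` is an areal percentage of
    rock/boulder cover and is never mixed arithmetically with the mass
    fractions.
    """

    mud: float
    sand: float
    gravel: float
    fine: float | None = None
    medium: float | None = None
    coarse: float | None = None
    hard_cover_pct: float | None = None

    def __post_init__(self):
        for name in ("mud", "sand", "gravel"):
            v = getattr(self, name)
            if not (-_SUM_TOL <= v <= 1.0 + _SUM_TOL):
                raise ValueError(f"{name} fraction {v} outside [0, 1]")
        total = self.mud + self.sand + self.gravel
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mud+sand+gravel = {total}, expected 1")
        subs = (self.fine, self.medium, self.coarse)
        if any(s is not None for s in subs):
            if any(s is None for s in subs):
                raise ValueError("give all three sand subfractions or none")
            if any(s < -_SUM_TOL for s in subs):
                raise ValueError("sand subfractions must be non-negative")
            if abs(sum(subs) - self.sand) > 1e-6:
                raise ValueError(
                    f"sand subfractions sum to {sum(subs)}, expected {self.sand}"
                )
        if self.hard_cover_pct is not None and not (0.0 <= self.hard_cover_pct <= 100.0):
            raise ValueError("hard_cover_pct outside [0, 100]")

    @property
    def mud_pct(self) -> float:
        return 100.0 * self.mud

    def sand_share_pct(self) -> float:
        """Sand as a percentage of the combined gravel and sand fraction."""
        gs = self.gravel + self.sand
        if gs <= 0.0:
            raise ZeroDivisionError("gravel + sand fraction is zero")
        return 100.0 * self.sand / gs

    def gravel_share_pct(self) -> float:
        """Gravel as a percentage of the combined gravel and sand fraction."""
        gs = self.gravel + self.sand
        if gs <= 0.0:
            raise ZeroDivisionError("gravel + sand fraction is zero")
        return 100.0 * self.gravel / gs


def classify_folk(comp: GrainSizeComposition) -> BshClass:
    """Classify a composition on the simplified Folk gravel–sand–mud triangle.

    Gravel tiers <5 / 5–30 / 30–80 / >80 % combined with sand:mud ratios
    1:9 / 1:1 / 9:1 yield the ten Level B classes; the Level A group
    follows from the Level B class.  Peat and lag sediment are not
    granulometric classes and are never returned here.
    """
    tol = 1e-12  # cross-multiplied ratio tests, robust at exact boundaries
    g = comp.gravel * 100.0
    # sand:mud ratio bands split at 1:9, 1:1 and 9:1 (upper band inclusive)
    if 9.0 * comp.sand < comp.mud - tol:
        band = 0
    elif comp.sand < comp.mud - tol:
        band = 1
    elif comp.sand < 9.0 * comp.mud - tol:
        band = 2
    else:
        band = 3

    if g >= 80.0 - tol:
        level_b = "G"
    elif g >= 30.0 - tol:
        level_b = ("mG", "mG", "msG", "sG")[band]
    elif g >= 5.0 - tol:
        level_b = ("gM", "gM", "msG", "gS")[band]
    else:
        level_b = ("M", "sM", "mS", "S")[band]

    for level_a, members in LEVEL_A_TO_B.items():
        if level_b in members and level_a != "not specified":
            return BshClass(level_a=level_a, level_b=level_b)
    raise AssertionError("unreachable")


def classify_figge_sand(comp: GrainSizeComposition) -> str:
    """Subdivide a sand (Level A ``S``) sample into fSa/mSa/cSa/mxSa.

    A subfraction holding at least half the sand mass names the class;
    without such a majority the sand is mixed (``mxSa``).
    """
    if classify_folk(comp).level_a != "S":
        raise ValueError("Level C subdivision is defined for Level A 'S' only")
    if comp.fine is None:
        raise ValueError("sand subfractions required for Level C classification")
    if comp.sand <= 0.0:
        raise ValueError("sand fraction is zero")
    shares = {
        "fSa": comp.fine / comp.sand,
        "mSa": comp.medium / comp.sand,
        "cSa": comp.coarse / comp.sand,
    }
    winner = max(shares, key=shares.get)
    return winner if shares[winner] >= 0.5 else "mxSa"


def classify_eunis(
    comp: GrainSizeComposition, thresholds: EunisThresholds = EunisThresholds()
) -> EunisSubstrate:
    """Assign the EUNIS substrate category of a composition.

    The areal hard-cover test takes precedence when hard cover is known:
    above 90 % cover the cell is rock/biogenic reef, within [10, 90] it
    is mixed sediment.  Otherwise granulometry decides: mud at >=20 %
    fines, else coarse sediment when gravel exceeds 30 % of gravel+sand,
    else sand when sand exceeds 70 % of gravel+sand.
    """
    t = thresholds
    if comp.hard_cover_pct is not None:
        if comp.hard_cover_pct > t.pure_min_pct:
            return EunisSubstrate.ROCK_BIOGENIC_REEF
        if t.mixed_hard_min_pct <= comp.hard_cover_pct <= t.mixed_hard_max_pct:
            return EunisSubstrate.MIXED_SEDIMENT_HARD

    # comparisons carry a 1e-9 percentage-point tolerance so that exact
    # threshold compositions keep their documented boundary semantics
    # (mud inclusive, shares strict) despite float rounding
    tol = 1e-9
    if comp.mud_pct >= t.mud_min_pct - tol:
        return EunisSubstrate.MUD
    if comp.gravel + comp.sand <= 0.0:
        raise ValueError(
            "gravel+sand fraction is zero below the mud threshold; shares undefined"
        )
    if comp.gravel_share_pct() > t.gravel_share_min_pct + tol:
        return EunisSubstrate.COARSE_SEDIMENT
    if comp.sand_share_pct() > t.sand_share_min_pct + tol:
        return EunisSubstrate.SAND
    # Exact boundary (gravel share == 30, sand share == 70): neither strict
    # test fires, so neither pure class applies; fall back to the mixed class.
    log.info(
        "composition on the coarse/sand share boundary resolved as mixed sediment"
    )
    return EunisSubstrate.MIXED_SEDIMENT_HARD


def classify_full(comp: GrainSizeComposition) -> tuple[BshClass, EunisSubstrate]:
    """Folk + Figge + EUNIS classification of one sample."""
    folk = classify_folk(comp)
    if folk.level_a == "S" and comp.fine is not None:
        folk = BshClass(folk.level_a, folk.level_b, classify_figge_sand(comp))
    return folk, classify_eunis(comp)


TAUBER_TO_EUNIS = {
    "gravel, very coarse sand": EunisSubstrate.COARSE_SEDIMENT,
    "fine sand—coarse sand": EunisSubstrate.SAND,
    "very fine mud—very fine sand": EunisSubstrate.MUD,
    "clay, peat, lag sediment/till": EunisSubstrate.MIXED_SEDIMENT_HARD,
}


def translate_tauber(tauber_class: str) -> EunisSubstrate:
    """Translate a legacy soft-bottom map class to its EUNIS substrate."""
    key = tauber_class.strip().replace("--", "—").replace(" - ", "—")
    if key not in TAUBER_TO_EUNIS:
        raise KeyError(
            f"unknown sediment map class {tauber_class!r}; "
            f"valid classes: {sorted(TAUBER_TO_EUNIS)}"
        )
    return TAUBER_TO_EUNIS[key]
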
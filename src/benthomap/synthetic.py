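"""Seeded synthetic seascapes with a known community-generating rule.

Every downstream stage (sediment classification, hard-bottom rules,
station labelling, predictive modelling, map composition) can be tested
against a recoverable ground truth: environmental predictor rasters are
linear gradients plus seeded smoothed noise, sediment patches come from
a thresholded random field, boulders from a per-class Poisson process,
and station observations (grab biomass tables, video cover tables) are
drawn around the target shares dictated by a :class:`CommunityRule`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .hardbottom import GridGeometry, classify_boulder_density_grid

__all__ = [
    "PREDICTOR_LAYERS",
    "GradientSpec",
    "SeascapeConfig",
    "RuleClause",
    "CommunityRule",
    "Seascape",
    "generate_environment",
    "generate_sediment_and_boulders",
    "generate_stations",
    "generate_seascape",
    "TOKEN_TO_TAXON",
]

#: Predictor layers available on every seascape.
PREDICTOR_LAYERS = [
    "depth",
    "salinity",
    "temperature",
    "current_velocity",
    "shear_stress",
    "par",
    "oxygen",
    "hypoxic_days",
    "doc",
    "ammonium",
    "nitrate",
    "phosphate",
]

#: Sediment class names accepted by the generator (Level A/B vocabulary
#: plus lag sediment and peat).
SEDIMENT_VOCABULARY = {
    "Fsed", "S", "Csed", "MxSed", "Peat", "LagSed",
    "M", "sM", "mS", "gS", "sG", "G", "gM", "msG", "mG",
}

#: Representative dominant taxon used when synthesising a station for a
#: community token; tokens without a dominant map to None.
TOKEN_TO_TAXON = {
    "3L3": "Arctica islandica",
    "3L1": "Macoma balthica",
    "3L9": "Cerastoderma glaucum",
    "3L4": "Mya arenaria",
    "3": None,
    "1E1": "Mytilidae",
    "1C3": "foliose red algae",
    "1C1": "Fucus",
    "1G1": "Hydrozoa",
    "1S1": "filamentous annual algae",
    "2T": None,
}

_FILLER_TAXA = ("Hediste diversicolor", "Peringia ulvae", "Gammarus salinus")
_FILLER_EPI = ("Balanidae", "Electra crustulenta")


@dataclass(frozen=True)
class GradientSpec:
    """A linear gradient: ``mean`` at the field centre, total span
    ``range`` along ``orientation`` ('we' grows west->east, 'ew' decays
    west->east, 'ns' grows north->south, 'sn' decays), plus smoothed
    Gaussian noise of standard deviation ``noise_sd``."""

    mean: float
    range: float = 0.0
    orientation: str = "we"
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.orientation not in ("we", "ew", "ns", "sn"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


def _default_gradients() -> dict[str, GradientSpec]:
    return {
        "depth": GradientSpec(mean=25.0, range=30.0, orientation="ns", noise_sd=1.0),
        "salinity": GradientSpec(mean=14.0, range=12.0, orientation="ew", noise_sd=0.3),
        "temperature": GradientSpec(mean=8.0, range=2.0, orientation="sn", noise_sd=0.2),
        "current_velocity": GradientSpec(mean=0.2, range=0.0, noise_sd=0.05),
        "shear_stress": GradientSpec(mean=0.1, range=0.0, noise_sd=0.02),
        "par": GradientSpec(mean=5.0, range=4.0, orientation="ns", noise_sd=0.3),
        "oxygen": GradientSpec(mean=8.0, range=0.0, noise_sd=0.5),
        "hypoxic_days": GradientSpec(mean=5.0, range=0.0, noise_sd=1.0),
        "doc": GradientSpec(mean=4.0, range=2.0, orientation="we", noise_sd=0.2),
        "ammonium": GradientSpec(mean=1.0, range=0.0, noise_sd=0.1),
        "nitrate": GradientSpec(mean=2.0, range=0.0, noise_sd=0.2),
        "phosphate": GradientSpec(mean=0.5, range=0.0, noise_sd=0.05),
    }


@dataclass(frozen=True)
class SeascapeConfig:
    """Parameters of one synthetic seascape realisation."""

    extent: float = 10_000.0  # metres, square
    cell_size: float = 1000.0  # 50 or 1000 typically
    seed: int = 0
    gradients: dict = field(default_factory=_default_gradients)
    sediment_classes: tuple[str, ...] = ("M", "S", "gS", "LagSed")
    sediment_weights: tuple[float, ...] = (0.3, 0.4, 0.15, 0.15)
    patch_scale: float = 2.0  # smoothing radius in cells
    boulder_intensity: dict = field(
        default_factory=lambda: {"M": 0.0, "S": 0.02, "gS": 0.5, "LagSed": 6.0}
    )
    n_grab: int = 200
    n_video: int = 60
    biomass_concentration: float = 0.0  # 0 => noise-free shares
    cover_noise_sd: float = 0.0
    photic_depth: float = 20.0  # cells shallower than this are photic

    def __post_init__(self):
        if self.extent <= 0 or self.cell_size <= 0:
            raise ValueError("extent and cell size must be positive")
        n = self.extent / self.cell_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cell size must divide the extent exactly")
        unknown = set(self.sediment_classes) - SEDIMENT_VOCABULARY
        if unknown:
            raise ValueError(
                f"unknown sediment class(es) {sorted(unknown)}; "
                f"vocabulary: {sorted(SEDIMENT_VOCABULARY)}"
            )
        if len(self.sediment_weights) != len(self.sediment_classes):
            raise ValueError("one weight per sediment class required")
        if abs(sum(self.sediment_weights) - 1.0) > 1e-9:
            raise ValueError("sediment weights must sum to 1")

    @property
    def n_cells(self) -> int:
        return int(round(self.extent / self.cell_size))

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(
            x0=0.0, y0=self.extent, cell_size=self.cell_size,
            n_rows=self.n_cells, n_cols=self.n_cells,
        )


# ---------------------------------------------------------------------------
# Community rule
# ---------------------------------------------------------------------------

_SEDIMENT_GROUP = {
    "Fsed": "mud", "M": "mud", "sM": "mud", "mS": "mud",
    "S": "sand",
    "Csed": "coarse", "gS": "coarse", "sG": "coarse", "G": "coarse",
    "MxSed": "coarse", "gM": "coarse", "msG": "coarse", "mG": "coarse",
    "LagSed": "lag", "Peat": "peat",
}


@dataclass(frozen=True)
class RuleClause:
    """First matching clause assigns the label distribution."""

    labels: dict  # token -> probability
    sediments: frozenset | None = None  # sediment groups, None = any
    salinity: tuple[float, float] = (-np.inf, np.inf)
    depth: tuple[float, float] = (-np.inf, np.inf)
    doc: tuple[float, float] = (-np.inf, np.inf)
    hard: bool | None = None

    def __post_init__(self):
        if abs(sum(self.labels.values()) - 1.0) > 1e-9:
            raise ValueError("label probabilities must sum to 1")

    def matches(self, sediment, salinity, depth, doc, hard) -> bool:
        group = _SEDIMENT_GROUP[sediment]
        if self.sediments is not None and group not in self.sediments:
            return False
        if self.hard is not None and hard != self.hard:
            return False
        return (
            self.salinity[0] <= salinity < self.salinity[1]
            and self.depth[0] <= depth < self.depth[1]
            and self.doc[0] <= doc < self.doc[1]
        )


@dataclass(frozen=True)
class CommunityRule:
    """Maps station conditions to community-label distributions.

    One clause list per realm; the first matching clause wins.  In
    deterministic mode the argmax label of the matched distribution is
    returned, which makes the generated ground truth exactly
    recoverable.
    """

    endo: tuple[RuleClause, ...]
    epi: tuple[RuleClause, ...]

    def distribution(self, realm, sediment, salinity, depth, doc, hard) -> dict:
        clauses = self.endo if realm == "endo" else self.epi
        for clause in clauses:
            if clause.matches(sediment, salinity, depth, doc, hard):
                return clause.labels
        raise LookupError(
            f"community rule has no clause for realm={realm}, "
            f"sediment={sediment}, salinity={salinity:.2f}, depth={depth:.2f}, "
            f"doc={doc:.2f}, hard={hard}"
        )

    def label(
        self, realm, sediment, salinity, depth, doc, hard,
        deterministic: bool = True, rng: np.random.Generator | None = None,
    ) -> str:
        dist = self.distribution(realm, sediment, salinity, depth, doc, hard)
        if deterministic:
            return max(dist, key=dist.get)
        if rng is None:
            raise ValueError("stochastic labelling needs an rng")
        tokens = sorted(dist)
        return rng.choice(tokens, p=[dist[t] for t in tokens])

    @classmethod
    def default(cls) -> "CommunityRule":
        """Salinity/depth/sediment-driven rule over five endo and three
        epi communities."""
        endo = (
            RuleClause(sediments=frozenset({"mud"}), depth=(25.0, np.inf),
                       labels={"3L3": 1.0}),
            RuleClause(sediments=frozenset({"mud"}), labels={"3L1": 1.0}),
            RuleClause(sediments=frozenset({"sand", "coarse", "lag"}),
                       salinity=(12.0, np.inf), labels={"3L9": 1.0}),
            RuleClause(sediments=frozenset({"sand", "coarse", "lag"}),
                       labels={"3": 1.0}),
        )
        epi = (
            RuleClause(salinity=(12.0, np.inf), depth=(15.0, np.inf),
                       labels={"1C3": 1.0}),
            RuleClause(salinity=(12.0, np.inf), labels={"1E1": 1.0}),
            RuleClause(labels={"1E1": 1.0}),
        )
        return cls(endo=endo, epi=epi)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_environment(config: SeascapeConfig) -> dict[str, np.ndarray]:
    """One raster per predictor layer.

    Noise is demeaned along the gradient axis so that column (or row)
    means follow the configured gradient exactly; depth is clipped at 0.
    """
    n = config.n_cells
    rng = np.random.default_rng(config.seed)
    stack: dict[str, np.ndarray] = {}
    for name in PREDICTOR_LAYERS:
        spec = config.gradients.get(name, GradientSpec(mean=0.0))
        ramp = np.linspace(-0.5, 0.5, n) * spec.range
        if spec.orientation in ("ew", "sn"):
            ramp = -ramp
        if spec.orientation in ("we", "ew"):
            base = np.tile(spec.mean + ramp, (n, 1))
            axis = 0  # demean each column
        else:
            base = np.tile((spec.mean + ramp)[:, None], (1, n))
            axis = 1  # demean each row
        field = base
        if spec.noise_sd > 0:
            noise = rng.normal(0.0, spec.noise_sd, size=(n, n))
            noise = ndimage.gaussian_filter(noise, sigma=config.patch_scale, mode="nearest")
            # renormalise after smoothing, then constrain orthogonal to the gradient
            sd = noise.std()
            if sd > 0:
                noise *= spec.noise_sd / sd
            noise -= noise.mean(axis=axis, keepdims=True)
            field = base + noise
        if name == "depth":
            field = np.clip(field, 0.0, None)
        stack[name] = field
    return stack


def generate_sediment_and_boulders(
    config: SeascapeConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Patchy sediment grid (class names) and boulder points (n, 2).

    Sediment patches are quantile bins of a smoothed random field, so
    requested class weights are met exactly up to rounding; boulder
    counts per cell are Poisson with the class intensity and positions
    are uniform within their cell.
    """
    n = config.n_cells
    rng = np.random.default_rng(config.seed + 1)
    base = rng.normal(size=(n, n))
    smooth = ndimage.gaussian_filter(base, sigma=config.patch_scale, mode="nearest")
    order = np.argsort(smooth, axis=None, kind="stable")
    sediment = np.empty(n * n, dtype=object)
    cuts = np.cumsum(np.round(np.array(config.sediment_weights) * n * n)).astype(int)
    cuts[-1] = n * n
    start = 0
    for cls, stop in zip(config.sediment_classes, cuts):
        sediment[order[start:stop]] = cls
        start = stop
    sediment = sediment.reshape(n, n)

    grid = config.grid
    points = []
    for cls in config.sediment_classes:
        lam = float(config.boulder_intensity.get(cls, 0.0))
        if lam < 0:
            raise ValueError("boulder intensity must be non-negative")
    for row in range(n):
        for col in range(n):
            lam = float(config.boulder_intensity.get(sediment[row, col], 0.0))
            if lam == 0.0:
                continue
            k = rng.poisson(lam)
            if k:
                x0 = grid.x0 + col * grid.cell_size
                y1 = grid.y0 - row * grid.cell_size
                xs = x0 + rng.random(k) * grid.cell_size
                ys = y1 - rng.random(k) * grid.cell_size
                points.extend(zip(xs, ys))
    return sediment, np.array(points, dtype=float).reshape(-1, 2)


def _hard_grid(config: SeascapeConfig, sediment: np.ndarray, boulders: np.ndarray):
    from .hardbottom import grid_boulder_counts

    counts = grid_boulder_counts(boulders, config.grid)
    classes = classify_boulder_density_grid(counts)
    return (classes == 3) | ((classes == 2) & (sediment == "LagSed")), classes


def generate_stations(
    config: SeascapeConfig,
    sediment: np.ndarray,
    environment: dict[str, np.ndarray],
    rule: CommunityRule,
    boulders: np.ndarray | None = None,
) -> pd.DataFrame:
    """Synthesise grab and video stations with stored true labels.

    Stations are spread over cells stratified by sediment class.  Grab
    stations carry a taxon biomass table whose dominant taxon realises
    the rule's label (Dirichlet noise when ``biomass_concentration`` >
    0); video stations carry percent covers (truncated-normal noise).
    Returns a long table: one row per station x taxon, plus columns
    ``true_label`` and ``hard_cover_pct``.
    """
    if config.n_grab < 0 or config.n_video < 0:
        raise ValueError("station counts must be non-negative")
    rng = np.random.default_rng(config.seed + 2)
    grid = config.grid
    hard, _ = _hard_grid(
        config, sediment,
        boulders if boulders is not None else np.empty((0, 2)),
    )

    def pick_cells(count: int, mask: np.ndarray | None = None) -> list[tuple[int, int]]:
        """Round-robin across sediment classes, uniform within a class."""
        cells_by_class: dict[str, list] = {}
        rows, cols = np.indices(sediment.shape)
        for cls in config.sediment_classes:
            sel = sediment == cls
            if mask is not None:
                sel &= mask
            cells_by_class[cls] = list(zip(rows[sel], cols[sel]))
        available = [c for c in config.sediment_classes if cells_by_class[c]]
        if not available:
            return []
        chosen = []
        i = 0
        while len(chosen) < count:
            cls = available[i % len(available)]
            pool = cells_by_class[cls]
            chosen.append(pool[rng.integers(len(pool))])
            i += 1
        return chosen

    records = []
    station_no = 0

    def conditions(row: int, col: int) -> dict:
        return dict(
            sediment=str(sediment[row, col]),
            salinity=float(environment["salinity"][row, col]),
            depth=float(environment["depth"][row, col]),
            doc=float(environment["doc"][row, col]),
        )

    for row, col in pick_cells(config.n_grab):
        station_no += 1
        cond = conditions(row, col)
        label = rule.label(realm="endo", hard=bool(hard[row, col]), **cond)
        dominant = TOKEN_TO_TAXON.get(label)
        if dominant is not None:
            shares = {dominant: 0.7}
            for i, filler in enumerate(_FILLER_TAXA):
                shares[filler] = 0.3 / len(_FILLER_TAXA)
        else:  # no dominant taxon: balanced community
            shares = {t: 1.0 / len(_FILLER_TAXA) for t in _FILLER_TAXA}
        taxa = sorted(shares)
        target = np.array([shares[t] for t in taxa])
        if config.biomass_concentration > 0:
            target = rng.dirichlet(target * config.biomass_concentration)
        total_biomass = 20.0  # grams, arbitrary scale
        x = grid.x0 + (col + 0.5) * grid.cell_size
        y = grid.y0 - (row + 0.5) * grid.cell_size
        for taxon, share in zip(taxa, target):
            records.append(
                dict(
                    station_id=f"GR{station_no:04d}", x=x, y=y, method="grab",
                    taxon=taxon, value=total_biomass * share,
                    hard_cover_pct=np.nan, true_label=label,
                    row=row, col=col,
                )
            )

    for row, col in pick_cells(config.n_video, mask=hard if hard.any() else None):
        station_no += 1
        cond = conditions(row, col)
        label = rule.label(realm="epi", hard=bool(hard[row, col]), **cond)
        dominant = TOKEN_TO_TAXON.get(label)
        hard_cover = 60.0 if hard[row, col] else 5.0
        covers = {}
        if dominant is not None:
            covers[dominant] = 40.0
        for filler in _FILLER_EPI:
            covers[filler] = 3.0
        if config.cover_noise_sd > 0:
            for taxon in covers:
                covers[taxon] = float(
                    np.clip(rng.normal(covers[taxon], config.cover_noise_sd), 0.0, 100.0)
                )
        x = grid.x0 + (col + 0.5) * grid.cell_size
        y = grid.y0 - (row + 0.5) * grid.cell_size
        for taxon, pct in sorted(covers.items()):
            records.append(
                dict(
                    station_id=f"VI{station_no:04d}", x=x, y=y, method="video",
                    taxon=taxon, value=pct, hard_cover_pct=hard_cover,
                    true_label=label, row=row, col=col,
                )
            )

    columns = [
        "station_id", "x", "y", "method", "taxon", "value",
        "hard_cover_pct", "true_label", "row", "col",
    ]
    return pd.DataFrame.from_records(records, columns=columns)


@dataclass(frozen=True)
class Seascape:
    """A fully generated synthetic seascape."""

    config: SeascapeConfig
    environment: dict
    sediment: np.ndarray
    boulders: np.ndarray
    stations: pd.DataFrame
    hard: np.ndarray
    boulder_classes: np.ndarray
    photic: np.ndarray

    @property
    def grid(self) -> GridGeometry:
        return self.config.grid


def generate_seascape(
    config: SeascapeConfig, rule: CommunityRule | None = None
) -> Seascape:
    """Run all generators with one config; deterministic per seed."""
    rule = rule or CommunityRule.default()
    environment = generate_environment(config)
    sediment, boulders = generate_sediment_and_boulders(config)
    hard, boulder_classes = _hard_grid(config, sediment, boulders)
    stations = generate_stations(config, sediment, environment, rule, boulders)
    photic = environment["depth"] < config.photic_depth
    return Seascape(
        config=config, environment=environment, sediment=sediment,
        boulders=boulders, stations=stations, hard=hard,
        boulder_classes=boulder_classes, photic=photic,
    )
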
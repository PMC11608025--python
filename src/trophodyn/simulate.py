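"""Synthetic species catalogs and multi-decade catch tables with known truth.

The generator emulates the structure of a national fisheries statistical
yearbook: ~100 species spanning trophic levels ~2.0-4.5 across four
migratory classes (tuna, oceanic migratory, seasonal migratory, indigenous),
annual landings 1970-2021 split between a coastal and an offshore sector,
with per-class exponential trends and multiplicative log-normal noise.

A dedicated *fishing-down* regime reshapes the indigenous assemblage so that
species above the class-median trophic level decay exponentially while those
below absorb the released mass (total indigenous catch constant in the
noiseless limit) — the canonical catch-composition signature of fishing down
the food web, with an analytically known MTL trajectory.

Noise is multiplicative log-normal with a mean-preserving correction
(log-mean −σ²/2), so the noiseless trajectory is the expectation of the
noisy one. Every species draws from its own substream keyed by a stable hash
of its species_id, so adding a species never perturbs the others. The
structural draws (trophic levels, per-species base catches) come from a
fixed root stream so that the ground truth depends on the configuration
alone: changing ``seed`` re-rolls only the observation noise, and replicate
tables share one analytic truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import MIGRATORY_CLASSES, catalog_from_dataframe, normalize_species_id
from .trends import fit_linear_trend

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_catalog",
    "generate_catch_table",
    "generate_fishing_down_dataset",
]

_GENUS = {
    "tuna": "Thunnosim",
    "oceanic_migratory": "Oceanosim",
    "seasonal_migratory": "Seasonosim",
    "indigenous": "Indigenosim",
}

# substream tags, so catalog / base-catch / noise draws never collide
_TAG_CATALOG = 0
_TAG_BASE = 1
_TAG_NOISE = 2

# root entropy for the structural (seed-independent) draws
_STRUCT_ROOT = 0x7D0FF15


def _default_proportions() -> dict:
    # mirrors the excluded-list sizes of the packaged scenarios:
    # 5 tuna / 13 oceanic / 19 seasonal of ~100, remainder indigenous
    return {
        "tuna": 0.05,
        "oceanic_migratory": 0.13,
        "seasonal_migratory": 0.19,
        "indigenous": 0.63,
    }


def _default_tl_ranges() -> dict:
    return {
        "tuna": (3.9, 4.5),
        "oceanic_migratory": (3.5, 4.5),
        "seasonal_migratory": (2.8, 4.4),
        "indigenous": (2.0, 4.5),
    }


def _default_trends() -> dict:
    return {c: 0.0 for c in MIGRATORY_CLASSES}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic yearbook.

    Defaults: 52 annual records (1970-2021), 100 species in proportions
    5/13/19/63% across the four classes, per-species median base catch
    ``base_catch_scale`` tonnes/yr with log-normal heterogeneity across
    species (``base_spread_sigma`` on the log scale), multiplicative
    log-normal observation noise ``noise_sigma`` = 0.05, coastal share 15%
    of every species' catch (offshore dominates national totals), flat
    per-class trends, and a 2%/yr fishing-down rate when that regime is
    requested.
    """

    seed: int = 0
    years: tuple[int, int] = (1970, 2021)
    n_species: int = 100
    class_proportions: dict = field(default_factory=_default_proportions)
    tl_ranges: dict = field(default_factory=_default_tl_ranges)
    base_catch_scale: float = 1000.0
    base_spread_sigma: float = 1.0
    noise_sigma: float = 0.05
    class_trends: dict = field(default_factory=_default_trends)
    fishing_down_rate: float = 0.02
    sector_split: float = 0.15  # coastal fraction

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_proportions sum to {total}, expected 1")
        if any(p < 0 or p > 1 for p in self.class_proportions.values()):
            raise ConfigError("class_proportions must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.n_species < len(MIGRATORY_CLASSES):
            raise ConfigError(
                f"n_species must be >= {len(MIGRATORY_CLASSES)} (one per class)"
            )
        if self.base_catch_scale <= 0:
            raise ConfigError("base_catch_scale must be positive")
        if not 0.0 <= self.sector_split <= 1.0:
            raise ConfigError("sector_split must lie in [0, 1]")
        if self.years[0] > self.years[1]:
            raise ConfigError(f"invalid year range {self.years}")

    @property
    def year_index(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)


@dataclass
class SyntheticTruth:
    """Ground truth implied by a config: the noiseless (expected) catch
    trajectories, the analytic MTL trajectory they induce, its fitted
    per-decade slope, and the scenario retained-mass fractions."""

    noiseless: pd.DataFrame  # years × species, tonnes, sectors pooled
    tl: pd.Series  # species -> trophic level
    mtl: pd.Series  # analytic MTL trajectory (years)
    mtl_per_decade: float  # 10 × OLS slope of the analytic MTL trajectory
    retained_fraction_by_scenario: dict  # scenario name -> % of pooled mass

    def summary_dict(self) -> dict:
        return {
            "mtl_per_decade": float(self.mtl_per_decade),
            "mtl_first": float(self.mtl.iloc[0]),
            "mtl_last": float(self.mtl.iloc[-1]),
            "retained_fraction_by_scenario": {
                k: float(v) for k, v in self.retained_fraction_by_scenario.items()
            },
        }


def _species_rng(root: int, tag: int, species_id: str) -> np.random.Generator:
    key = zlib.crc32(species_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([root, tag, key]))


def _class_counts(cfg: SyntheticConfig) -> dict:
    """Largest-remainder apportionment of n_species across classes."""
    quotas = {c: cfg.n_species * cfg.class_proportions.get(c, 0.0) for c in MIGRATORY_CLASSES}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = cfg.n_species - sum(counts.values())
    by_remainder = sorted(
        MIGRATORY_CLASSES, key=lambda c: (-(quotas[c] - counts[c]), c)
    )
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def generate_catalog(cfg: SyntheticConfig) -> pd.DataFrame:
    """Deterministic synthetic species catalog for the given config."""
    counts = _class_counts(cfg)
    rows = []
    idx = 0
    for cls in MIGRATORY_CLASSES:
        lo, hi = cfg.tl_ranges[cls]
        for _ in range(counts[cls]):
            idx += 1
            name = f"{_GENUS[cls]} sp{idx:03d}"
            rng = _species_rng(_STRUCT_ROOT, _TAG_CATALOG, normalize_species_id(name))
            rows.append(
                {
                    "species_id": name,
                    "scientific_name": name,
                    "family": f"{_GENUS[cls]}idae",
                    "common_name": f"synthetic {cls} {idx}",
                    "trophic_level": rng.uniform(lo, hi),
                    "migratory_class": cls,
                    "excluded_taxon": False,
                }
            )
    return catalog_from_dataframe(pd.DataFrame(rows))


def _base_catches(catalog: pd.DataFrame, cfg: SyntheticConfig) -> pd.Series:
    base = {}
    for sid in catalog.index:
        rng = _species_rng(_STRUCT_ROOT, _TAG_BASE, sid)
        base[sid] = cfg.base_catch_scale * np.exp(cfg.base_spread_sigma * rng.normal())
    return pd.Series(base, name="base_catch")


def _noiseless_matrix(catalog: pd.DataFrame, cfg: SyntheticConfig) -> pd.DataFrame:
    """Expected catch (tonnes, sectors pooled) per year × species under the
    plain per-class exponential-trend regime."""
    years = cfg.year_index
    t = years - years[0]
    base = _base_catches(catalog, cfg)
    cols = {}
    for sid in catalog.index:
        rate = cfg.class_trends.get(catalog.loc[sid, "migratory_class"], 0.0)
        cols[sid] = base[sid] * np.exp(rate * t)
    return pd.DataFrame(cols, index=pd.Index(years, name="year"))


def _apply_fishing_down(
    noiseless: pd.DataFrame, catalog: pd.DataFrame, cfg: SyntheticConfig
) -> pd.DataFrame:
    """Reshape indigenous trajectories: above-median-TL species decay at
    fishing_down_rate; below-median species absorb the released mass so the
    class total is constant over time."""
    r = cfg.fishing_down_rate
    if r == 0.0:
        return noiseless
    ind = catalog.index[catalog["migratory_class"] == "indigenous"]
    if len(ind) < 2:
        raise ConfigError("fishing-down regime needs >= 2 indigenous species")
    tl = catalog.loc[ind, "trophic_level"]
    med = tl.median()
    high = list(ind[tl > med])
    low = list(ind[tl <= med])
    if not high or not low:
        raise ConfigError("fishing-down regime needs species on both sides of the median TL")

    years = noiseless.index.to_numpy()
    t = years - years[0]
    out = noiseless.copy()
    decay = np.exp(-r * t)
    high_base = noiseless.loc[:, high].iloc[0]
    low_base = noiseless.loc[:, low].iloc[0]
    high_total0 = high_base.sum()
    class_total = high_total0 + low_base.sum()

    for sid in high:
        out[sid] = high_base[sid] * decay
    low_total_t = class_total - high_total0 * decay  # released mass flows down
    if (low_total_t <= 0).any():
        raise ConfigError("fishing_down_rate produces non-positive low-TL catch")
    low_shares = low_base / low_base.sum()
    for sid in low:
        out[sid] = low_shares[sid] * low_total_t
    return out


def _truth_from_noiseless(
    noiseless: pd.DataFrame, catalog: pd.DataFrame
) -> SyntheticTruth:
    tl = catalog["trophic_level"].loc[noiseless.columns]
    mtl = (noiseless * tl).sum(axis=1) / noiseless.sum(axis=1)
    fit = fit_linear_trend(mtl)
    totals = noiseless.sum(axis=0)
    grand = totals.sum()
    cuts = {
        "scenario_all": (),
        "scenario_1": ("tuna",),
        "scenario_2": ("tuna", "oceanic_migratory"),
        "scenario_3": ("tuna", "oceanic_migratory", "seasonal_migratory"),
    }
    retained = {}
    for name, excluded in cuts.items():
        keep = [s for s in noiseless.columns if catalog.loc[s, "migratory_class"] not in excluded]
        retained[name] = 100.0 * totals[keep].sum() / grand
    return SyntheticTruth(
        noiseless=noiseless,
        tl=tl,
        mtl=mtl.rename("MTL"),
        mtl_per_decade=fit.per_decade_change,
        retained_fraction_by_scenario=retained,
    )


def _to_catch_table(noiseless: pd.DataFrame, cfg: SyntheticConfig) -> pd.DataFrame:
    """Apply per-species log-normal noise and the sector split; return the
    long-format catch table (tonnes)."""
    years = noiseless.index.to_numpy()
    sigma = cfg.noise_sigma
    frames = []
    for sid in noiseless.columns:
        traj = noiseless[sid].to_numpy()
        if sigma > 0:
            rng = _species_rng(cfg.seed, _TAG_NOISE, sid)
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(years)))
        else:
            noise = 1.0
        catch = traj * noise
        frames.append(
            pd.DataFrame(
                {
                    "year": np.concatenate([years, years]),
                    "sector": ["coastal"] * len(years) + ["offshore"] * len(years),
                    "species_id": sid,
                    "catch": np.concatenate(
                        [catch * cfg.sector_split, catch * (1.0 - cfg.sector_split)]
                    ),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table[table["catch"] > 0].reset_index(drop=True)


def generate_catch_table(
    catalog: pd.DataFrame, cfg: SyntheticConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Synthetic catch table under per-class exponential trends."""
    noiseless = _noiseless_matrix(catalog, cfg)
    return _to_catch_table(noiseless, cfg), _truth_from_noiseless(noiseless, catalog)


def generate_fishing_down_dataset(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Catalog + catch table + truth under the fishing-down regime.

    With ``fishing_down_rate=0`` this reduces exactly to
    :func:`generate_catch_table` on the config's catalog.
    """
    catalog = generate_catalog(cfg)
    noiseless = _apply_fishing_down(_noiseless_matrix(catalog, cfg), catalog, cfg)
    return catalog, _to_catch_table(noiseless, cfg), _truth_from_noiseless(noiseless, catalog)
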
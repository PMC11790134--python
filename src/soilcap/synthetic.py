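"""Synthetic soil-survey generator.

Emulates a stratified survey over five land-use classes (30 sites:
residential 5, commercial 7, educational 6, floodplain 7, agricultural 5)
with right-skewed metal concentrations. Per metal and stratum the values
are lognormal with moments matched to published per-land-use mean/SD, and
are driven by a smooth Gaussian random field over the site locations so
empirical variograms are non-degenerate. A companion generator plants a
known nonnegative factorization for source-apportionment recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LAND_USES, METALS, SoilSample, SoilSurvey, default_references

# Per-stratum concentration moments (mg/kg): {land_use: {metal: (mean, sd)}}.
# These are the study conditions the generator reproduces by default.
STRATUM_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "residential": {
        "Pb": (115.28, 38.96), "Cr": (67.74, 72.04), "Mn": (320.69, 42.16),
        "Cu": (17.09, 4.17), "Zn": (98.54, 36.10), "Co": (13.97, 3.58),
        "Ni": (22.56, 4.42), "As": (25.23, 6.00),
    },
    "commercial": {
        "Pb": (105.33, 28.30), "Cr": (72.19, 16.60), "Mn": (316.79, 42.51),
        "Cu": (22.51, 6.68), "Zn": (61.22, 45.70), "Co": (17.05, 2.06),
        "Ni": (26.51, 5.34), "As": (32.82, 16.77),
    },
    "educational": {
        "Pb": (155.77, 42.19), "Cr": (141.68, 63.21), "Mn": (300.58, 48.46),
        "Cu": (19.97, 4.40), "Zn": (92.80, 71.61), "Co": (11.30, 5.11),
        "Ni": (24.35, 3.78), "As": (27.89, 9.37),
    },
    "floodplain": {
        "Pb": (120.96, 16.52), "Cr": (553.68, 825.53), "Mn": (280.77, 207.95),
        "Cu": (21.54, 26.17), "Zn": (15.21, 3.44), "Co": (5.17, 1.20),
        "Ni": (22.49, 13.01), "As": (16.88, 4.68),
    },
    "agricultural": {
        "Pb": (173.71, 23.19), "Cr": (280.02, 492.62), "Mn": (286.70, 129.95),
        "Cu": (21.50, 14.93), "Zn": (64.68, 54.52), "Co": (10.92, 5.62),
        "Ni": (23.57, 9.36), "As": (28.33, 16.94),
    },
}

#: Survey design: sites per land-use stratum.
STRATUM_SIZES: dict[str, int] = {
    "residential": 5, "commercial": 7, "educational": 6,
    "floodplain": 7, "agricultural": 5,
}


class SpecError(ValueError):
    """Stratum specification violates an invariant."""


@dataclass(frozen=True)
class StratumSpec:
    """One land-use stratum: size, per-metal (mean, sd) and spatial extent."""

    land_use: str
    n_sites: int
    moments: dict[str, tuple[float, float]]
    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise SpecError(f"{self.land_use}: n_sites must be >= 1")
        for m, (mean, sd) in self.moments.items():
            if mean <= 0:
                raise SpecError(f"{self.land_use}/{m}: mean must be > 0")
            if sd < 0:
                raise SpecError(f"{self.land_use}/{m}: sd must be >= 0")
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise SpecError(f"{self.land_use}: degenerate extent")


@dataclass(frozen=True)
class PMFTruth:
    """Planted ground truth for factorization recovery tests."""

    G_true: np.ndarray  # n x p contributions, nonnegative
    F_true: np.ndarray  # p x m profiles, nonnegative
    noise_sd: np.ndarray  # n x m

    @property
    def X_true(self) -> np.ndarray:
        return self.G_true @ self.F_true

    @property
    def mass_split(self) -> np.ndarray:
        """True per-factor share of total apportioned mass (fractions)."""
        mass = np.einsum("ik,kj->k", self.G_true, self.F_true)
        return mass / mass.sum()


def default_stratum_specs(domain: tuple[float, float] = (2000.0, 2000.0),
                          ) -> list[StratumSpec]:
    """Default five-stratum design on a rectangular domain (metres).

    Strata are laid out as vertical bands across the domain (an arbitrary
    local planar origin; no CRS is implied).
    """
    width, height = domain
    specs = []
    n_strata = len(LAND_USES)
    band = width / n_strata
    for i, lu in enumerate(LAND_USES):
        specs.append(StratumSpec(
            land_use=lu,
            n_sites=STRATUM_SIZES[lu],
            moments=STRATUM_MOMENTS[lu],
            extent=(i * band, 0.0, (i + 1) * band, height),
        ))
    return specs


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic moments."""
    if sd == 0.0:
        return np.log(mean), 0.0
    s2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * s2
    return mu, np.sqrt(s2)


def _correlated_normals(coords: np.ndarray, corr_range: float,
                        rng: np.random.Generator, nugget: float = 0.2) -> np.ndarray:
    """Standard-normal field with exponential spatial correlation.

    Marginal variance is exactly 1 so lognormal moment matching survives the
    spatial structure; ``nugget`` is the uncorrelated variance fraction.
    """
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = (1.0 - nugget) * np.exp(-d / corr_range) + nugget * np.eye(n)
    # jitter for numerical PSD
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    return L @ rng.standard_normal(n)


def generate_survey(specs: list[StratumSpec] | None = None,
                    seed: int = 0,
                    references=None,
                    corr_range_fraction: float = 0.25) -> SoilSurvey:
    """Draw a stratified survey with spatially autocorrelated lognormal fields.

    Per metal, a unit-variance Gaussian random field with exponential
    covariance (range = ``corr_range_fraction`` of the overall extent) is
    sampled at the site locations and mapped through each stratum's
    moment-matched lognormal transform, so stratum moments are honoured
    while variograms remain fittable. Concentrations are clamped at half
    the method detection limit. ``corr_range_fraction = 0`` is the
    independent (pure-nugget) limit: sites are drawn i.i.d., which is the
    cheap path for large Monte-Carlo checks of the moment matching.
    """
    if specs is None:
        specs = default_stratum_specs()
    if not specs:
        raise SpecError("at least one stratum required")
    refs = references or default_references()
    rng = np.random.default_rng(seed)

    # site coordinates, stratum by stratum (order fixed by spec order)
    coords, land_use = [], []
    for sp in specs:
        xmin, ymin, xmax, ymax = sp.extent
        xs = rng.uniform(xmin, xmax, sp.n_sites)
        ys = rng.uniform(ymin, ymax, sp.n_sites)
        coords.append(np.column_stack([xs, ys]))
        land_use.extend([sp.land_use] * sp.n_sites)
    coords = np.vstack(coords)
    n = coords.shape[0]

    all_x = coords[:, 0]
    all_y = coords[:, 1]
    extent = max(all_x.max() - all_x.min(), all_y.max() - all_y.min(), 1.0)
    corr_range = corr_range_fraction * extent

    # per-metal correlated standard normals over all sites
    conc = np.empty((n, len(METALS)))
    for j, m in enumerate(METALS):
        if corr_range_fraction <= 0:
            z = rng.standard_normal(n)
        else:
            z = _correlated_normals(coords, corr_range, rng)
        row = 0
        for sp in specs:
            mean, sd = sp.moments[m]
            mu, sig = _lognormal_params(mean, sd)
            block = slice(row, row + sp.n_sites)
            conc[block, j] = np.exp(mu + sig * z[block])
            row += sp.n_sites
        conc[:, j] = np.maximum(conc[:, j], 0.5 * refs[m].mdl)

    samples = []
    for i in range(n):
        cmap = {m: float(conc[i, j]) for j, m in enumerate(METALS)}
        below = {m: cmap[m] <= refs[m].mdl for m in METALS}
        samples.append(SoilSample(
            site_id=f"S{i + 1}", x=float(coords[i, 0]), y=float(coords[i, 1]),
            land_use=land_use[i], conc=cmap, below_mdl=below))
    return SoilSurvey(samples)


def generate_pmf_dataset(n: int = 30, m: int = 8, p: int = 3,
                         noise_level: float = 0.05, seed: int = 0,
                         mass_split=None) -> tuple[SoilSurvey, PMFTruth]:
    """Plant a nonnegative factorization X = G.F + noise for recovery tests.

    Profiles F mimic distinct pollution-source fingerprints: the metals are
    partitioned across factors, each factor loading heavily on its own
    subset and weakly elsewhere (identifiability requires separated
    profiles), scaled to realistic metal magnitudes. Contributions G are
    gamma-distributed, with three near-pure sites per factor — sites
    dominated by a single source, as found next to point sources — which
    anchor the factorization (the "pure-pixel" identifiability condition).
    Gaussian noise with sd = ``noise_level`` x element magnitude is added
    and truncated at zero. ``mass_split`` (length-p fractions) rescales
    factors to a prescribed share of the total apportioned mass.
    """
    if p >= min(n, m):
        raise ValueError(f"p={p} must be < min(n, m)={min(n, m)}")
    if m < len(METALS):
        raise ValueError("m must cover all survey metals (>= 8)")
    metals = METALS[:m] if m <= len(METALS) else tuple(
        list(METALS) + [f"M{i}" for i in range(m - len(METALS))])
    rng = np.random.default_rng(seed)
    refs = default_references()
    scale = np.array([STRATUM_MOMENTS["residential"].get(mm, (50.0, 10.0))[0]
                      for mm in metals])

    # source-like fingerprints: each factor dominates a disjoint metal block
    owner = rng.permuted(np.arange(m) % p)
    F = rng.uniform(0.005, 0.04, (p, m))
    F[owner, np.arange(m)] = rng.uniform(0.6, 1.0, m)
    F *= scale[None, :]
    G = rng.gamma(shape=2.0, scale=0.5, size=(n, p))
    n_pure_per_factor = 3
    if n >= n_pure_per_factor * p:
        pure_sites = rng.choice(n, n_pure_per_factor * p, replace=False)
        for k in range(p):
            for i in pure_sites[k * n_pure_per_factor:(k + 1) * n_pure_per_factor]:
                G[i] *= 0.01
                G[i, k] = rng.uniform(1.5, 2.5)
    if mass_split is not None:
        target = np.asarray(mass_split, dtype=float)
        if target.shape != (p,) or not np.isclose(target.sum(), 1.0):
            raise ValueError("mass_split must be length-p fractions summing to 1")
        mass = np.einsum("ik,kj->k", G, F)
        G = G * (target * mass.sum() / mass)[None, :]

    X_true = G @ F
    noise_sd = noise_level * np.abs(X_true)
    X = np.maximum(X_true + rng.standard_normal((n, m)) * noise_sd, 0.0)

    samples = []
    lu_cycle = list(LAND_USES)
    for i in range(n):
        cmap = {mm: float(X[i, j]) for j, mm in enumerate(metals)}
        below = {mm: cmap[mm] <= refs[mm].mdl if mm in refs else False
                 for mm in metals}
        samples.append(SoilSample(
            site_id=f"S{i + 1}",
            x=float(rng.uniform(0, 2000)), y=float(rng.uniform(0, 2000)),
            land_use=lu_cycle[i % len(lu_cycle)],
            conc=cmap, below_mdl=below))
    survey = SoilSurvey(samples, metals=metals)
    return survey, PMFTruth(G_true=G, F_true=F, noise_sd=noise_sd)
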
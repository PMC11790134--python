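"""Domain types, reference-constant registry, and tabular I/O shared by all stages.

The package works on small stratified soil surveys: one row per sampling
site with planar coordinates (metres, projected), a land-use class and the
concentrations (mg/kg) of eight metal(loid)s: Pb, Cr, Mn, Cu, Zn, Co, Ni, As.
Per-metal reference constants (geochemical background, risk-screening value,
standard limit, Hakanson toxic-response factor, method detection limit and
relative analytical error) drive every index and the PMF uncertainty model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed metal ordering shared by every matrix in the pipeline.
METALS: tuple[str, ...] = ("Pb", "Cr", "Mn", "Cu", "Zn", "Co", "Ni", "As")

#: Land-use strata of the survey design.
LAND_USES: tuple[str, ...] = (
    "residential",
    "commercial",
    "educational",
    "floodplain",
    "agricultural",
)


class SchemaError(ValueError):
    """Input table does not have the expected columns/shape."""


class ValidationError(ValueError):
    """Input values violate a domain invariant (e.g. negative concentration)."""


class ReferenceError(ValueError):
    """Reference constants violate an invariant (e.g. Cs <= Cb)."""


@dataclass(frozen=True)
class MetalReference:
    """Per-metal reference constants.

    Parameters
    ----------
    metal : str
        Metal(loid) name, one of :data:`METALS`.
    background_cb : float
        Geochemical background concentration Cb (mg/kg).
    screening_cs : float
        Risk-screening value Cs (mg/kg); concentration at which the soil's
        residual capacity for the metal is exhausted. Must exceed Cb.
    standard_limit_sj : float
        Standard limit Sj (mg/kg) used by the single-metal Nemerow index.
    toxic_response_tr : float
        Hakanson toxic-response factor Tr (dimensionless).
    mdl : float
        Method detection limit (mg/kg).
    error_fraction_sigma : float
        Relative analytical standard deviation sigma_j used in the PMF
        uncertainty equation (dimensionless).
    """

    metal: str
    background_cb: float
    screening_cs: float
    standard_limit_sj: float
    toxic_response_tr: float
    mdl: float
    error_fraction_sigma: float

    def __post_init__(self) -> None:
        for name in ("background_cb", "screening_cs", "standard_limit_sj",
                     "toxic_response_tr", "mdl"):
            if getattr(self, name) <= 0:
                raise ReferenceError(f"{self.metal}: {name} must be > 0")
        if self.error_fraction_sigma < 0:
            raise ReferenceError(f"{self.metal}: error fraction must be >= 0")
        if self.screening_cs <= self.background_cb:
            raise ReferenceError(
                f"{self.metal}: screening value Cs={self.screening_cs} must "
                f"exceed background Cb={self.background_cb}"
            )


# FAO background values (mg/kg).
_BACKGROUND_CB = {"Pb": 50.0, "Cr": 100.0, "Mn": 2000.0, "Cu": 100.0,
                  "Zn": 300.0, "Co": 50.0, "Ni": 100.0, "As": 20.0}

# Instrument method detection limits (mg/kg); As reported as 0.3 ug/kg and
# converted to mg/kg here.
_MDL = {"Pb": 0.25, "Zn": 0.21, "Cr": 0.16, "Mn": 0.15, "Ni": 0.54,
        "Co": 0.12, "Cu": 0.05, "As": 0.0003}

# Hakanson toxic-response factors (literature defaults, configurable).
_TR = {"Pb": 5.0, "Cr": 2.0, "Mn": 1.0, "Cu": 5.0, "Zn": 1.0, "Co": 5.0,
       "Ni": 5.0, "As": 10.0}

# Default risk-screening values (mg/kg). Drawn from agricultural-soil
# screening standards where those exceed the FAO background; otherwise set
# above background so the capacity denominator Cs - Cb stays positive.
# These are documented, fully overridable defaults, not survey ground truth.
_SCREENING_CS = {"Pb": 400.0, "Cr": 350.0, "Mn": 3500.0, "Cu": 200.0,
                 "Zn": 500.0, "Co": 100.0, "Ni": 190.0, "As": 40.0}

#: Default relative analytical error fraction for the PMF uncertainty model.
DEFAULT_SIGMA = 0.1


def default_references(
    overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, MetalReference]:
    """Built-in reference table for the eight metals.

    ``overrides`` maps metal -> {field: value} and replaces individual
    constants (e.g. ``{"Pb": {"screening_cs": 400}}``). The standard limit
    Sj defaults to the screening value Cs.
    """
    refs: dict[str, MetalReference] = {}
    for m in METALS:
        kw = dict(
            metal=m,
            background_cb=_BACKGROUND_CB[m],
            screening_cs=_SCREENING_CS[m],
            standard_limit_sj=_SCREENING_CS[m],
            toxic_response_tr=_TR[m],
            mdl=_MDL[m],
            error_fraction_sigma=DEFAULT_SIGMA,
        )
        if overrides and m in overrides:
            kw.update(overrides[m])
        refs[m] = MetalReference(**kw)
    return refs


def read_references(path: str | Path) -> dict[str, MetalReference]:
    """Read a reference-constant CSV (columns: metal, Cb, Cs, Sj, Tr, MDL, sigma)."""
    df = pd.read_csv(path)
    cols = {"metal", "Cb", "Cs", "Sj", "Tr", "MDL", "sigma"}
    missing = cols - set(df.columns)
    if missing:
        raise SchemaError(f"reference table missing columns: {sorted(missing)}")
    refs = {}
    for _, row in df.iterrows():
        refs[row["metal"]] = MetalReference(
            metal=row["metal"],
            background_cb=float(row["Cb"]),
            screening_cs=float(row["Cs"]),
            standard_limit_sj=float(row["Sj"]),
            toxic_response_tr=float(row["Tr"]),
            mdl=float(row["MDL"]),
            error_fraction_sigma=float(row["sigma"]),
        )
    return refs


@dataclass(frozen=True)
class SoilSample:
    """One sampling site: id, planar coordinates, land use and concentrations."""

    site_id: str
    x: float
    y: float
    land_use: str
    conc: dict[str, float]
    below_mdl: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(METALS) - set(self.conc)
        if missing:
            raise ValidationError(f"site {self.site_id}: missing metals {sorted(missing)}")
        if self.land_use not in LAND_USES:
            raise ValidationError(
                f"site {self.site_id}: unknown land use {self.land_use!r}")
        for m, c in self.conc.items():
            if not np.isfinite(c) or c < 0:
                raise ValidationError(
                    f"site {self.site_id}: invalid concentration {m}={c}")


@dataclass
class SoilSurvey:
    """Ordered collection of :class:`SoilSample` with a fixed metal ordering."""

    samples: list[SoilSample]
    metals: tuple[str, ...] = METALS

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate site ids: {dupes}")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.samples]

    @property
    def coords(self) -> np.ndarray:
        """n x 2 array of (x, y)."""
        return np.array([[s.x, s.y] for s in self.samples], dtype=float)

    @property
    def land_use(self) -> np.ndarray:
        return np.array([s.land_use for s in self.samples])

    @property
    def X(self) -> np.ndarray:
        """n x m concentration matrix in the survey's metal order (mg/kg)."""
        return np.array([[s.conc[m] for m in self.metals] for s in self.samples])

    def values(self, metal: str) -> np.ndarray:
        return np.array([s.conc[metal] for s in self.samples])

    def subset(self, land_use: str) -> "SoilSurvey":
        picked = [s for s in self.samples if s.land_use == land_use]
        return SoilSurvey(picked, self.metals)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {"site": s.site_id, "x": s.x, "y": s.y, "land_use": s.land_use}
            row.update({m: s.conc[m] for m in self.metals})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Tunable parameters shared across stages.

    ``soil_mass_m`` is the soil weight per hectare of arable land (kg/ha);
    the capacity index Pi is invariant to it but the absolute capacities
    Qi/Qib are not. ``pi_class_bins`` maps the capacity index to risk
    classes with closed lower bounds on the upper class.
    """

    soil_mass_m: float = 2.25e6
    pi_class_bins: tuple[tuple[float, str], ...] = (
        (0.7, "safe"),
        (0.4, "precautionary"),
        (0.0, "loaded"),
    )
    pi_overloaded_label: str = "overloaded"
    contamination_pi_threshold: float = 1.0
    integrated_pi_threshold: float = 0.4
    grid_ncells: int = 100
    random_seed: int = 0
    pmf_p_range: tuple[int, ...] = (3, 4, 5)
    pmf_n_runs: int = 20
    pmf_max_iter: int = 5000
    pmf_tol: float = 1e-6
    som_rows: int | None = None
    som_cols: int | None = None
    som_epochs: int = 50
    ebk_ensemble: int = 50

    def __post_init__(self) -> None:
        edges = [e for e, _ in self.pi_class_bins]
        if any(a <= b for a, b in zip(edges, edges[1:])):
            raise ValueError("pi_class_bins must be strictly decreasing")
        if self.grid_ncells <= 0:
            raise ValueError("grid_ncells must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "pi_class_bins" in raw:
            raw["pi_class_bins"] = tuple(
                (float(e), str(lbl)) for e, lbl in raw["pi_class_bins"])
        for tup in ("pmf_p_range",):
            if tup in raw:
                raw[tup] = tuple(int(v) for v in raw[tup])
        return cls(**raw)


_REQUIRED_COLUMNS = ("site", "x", "y", "land_use") + METALS


def read_survey(path: str | Path, format: str | None = None,
                references: Mapping[str, MetalReference] | None = None) -> SoilSurvey:
    """Read a survey table (CSV or XLSX) into a validated :class:`SoilSurvey`.

    Expected columns: ``site, x, y, land_use`` plus the eight metals.
    Concentrations are mg/kg. Rows with unparsable or negative
    concentrations are rejected with their row index. Values at or below
    the method detection limit are flagged ``below_mdl`` when a reference
    table is supplied.
    """
    path = Path(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv"
    try:
        if format == "xlsx":
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path)
    except Exception as exc:  # includes EmptyDataError
        raise SchemaError(f"cannot read survey table {path}: {exc}") from exc
    if df.empty:
        raise SchemaError(f"survey table {path} has no data rows")
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"survey table missing columns: {sorted(missing)}")
    refs = references or default_references()
    samples = []
    for idx, row in df.iterrows():
        conc = {}
        for m in METALS:
            try:
                c = float(row[m])
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"row {idx}: unparsable {m} value {row[m]!r}") from exc
            if not np.isfinite(c) or c < 0:
                raise ValidationError(f"row {idx}: invalid {m} concentration {c}")
            conc[m] = c
        below = {m: conc[m] <= refs[m].mdl for m in METALS}
        samples.append(SoilSample(
            site_id=str(row["site"]), x=float(row["x"]), y=float(row["y"]),
            land_use=str(row["land_use"]), conc=conc, below_mdl=below))
    return SoilSurvey(samples)


def write_survey(survey: SoilSurvey, path: str | Path) -> None:
    """Write a survey to CSV in the canonical column order (full precision)."""
    survey.to_frame().to_csv(path, index=False)


def write_table(rows: pd.DataFrame, path: str | Path,
                float_format: str = "%.4g") -> None:
    """Write a result table to CSV with 4-significant-digit numeric formatting.

    Deterministic inputs produce byte-identical files.
    """
    if rows is None or len(rows) == 0:
        raise ValueError("refusing to write an empty result table")
    rows.to_csv(path, index=False, float_format=float_format)


def sites_geojson(survey: SoilSurvey, properties: pd.DataFrame | None = None) -> dict:
    """GeoJSON FeatureCollection of sites, optionally with per-site attributes."""
    feats = []
    for i, s in enumerate(survey.samples):
        props = {"site": s.site_id, "land_use": s.land_use}
        props.update({m: s.conc[m] for m in survey.metals})
        if properties is not None:
            props.update(properties.iloc[i].to_dict())
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [s.x, s.y]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": feats}
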
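"""Pollution and capacity indices per site and metal.

Implements the standard single-metal indices of soil geochemistry —
contamination factor CF = Ci/Cb, Hakanson ecological risk ER = Tr*CF, the
single-metal Nemerow ratio NPI = Ci/Sj — and the environmental pollution
capacity (EPC) index

    Qi  = 1e-6 * M * (Cs - Ci)        existing capacity (per hectare)
    Qib = 1e-6 * M * (Cs - Cb)        total capacity at background
    Pi  = Qi / Qib = (Cs - Ci) / (Cs - Cb)

so Pi = 1 for background soil, 0 when the screening value Cs is reached and
negative beyond it. Pi is independent of the soil mass M. Per-site
integration uses min-emphasizing Nemerow combinations: concentrations are
combined through sqrt((mean^2 + max^2)/2) on NPI, while capacity values are
first range-normalized to [0, 1] across the survey and then combined with
sqrt((mean^2 + min^2)/2), emphasizing the metal with the least residual
capacity.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .core import (MetalReference, PipelineConfig, ReferenceError, SoilSurvey,
                   default_references)


def contamination_factor(ci: float, cb: float) -> float:
    """CF = Ci / Cb, measured concentration over geochemical background."""
    if cb <= 0:
        raise ReferenceError("background Cb must be > 0")
    return ci / cb


def ecological_risk(tr: float, cf: float) -> float:
    """ER = Tr * CF (Hakanson single-element ecological risk)."""
    if tr <= 0:
        raise ReferenceError("toxic response factor Tr must be > 0")
    return tr * cf


def nemerow_single(ci: float, sj: float) -> float:
    """Single-metal Nemerow ratio NPI = Ci / Sj."""
    if sj <= 0:
        raise ReferenceError("standard limit Sj must be > 0")
    return ci / sj


def nemerow_integrated(npis) -> float:
    """Max-emphasizing Nemerow combination sqrt((mean^2 + max^2) / 2)."""
    arr = np.asarray(npis, dtype=float)
    if arr.size == 0:
        raise ValueError("nemerow_integrated requires at least one value")
    return float(np.sqrt((arr.mean() ** 2 + arr.max() ** 2) / 2.0))


def capacity_pi(ci: float, cs: float, cb: float,
                m_soil: float = 2.25e6) -> tuple[float, float, float]:
    """Environmental pollution capacity (Qi, Qib, Pi) for one site and metal.

    ``m_soil`` is the soil weight per hectare (kg/ha); Pi = Qi/Qib cancels it.
    """
    if cs <= cb:
        raise ReferenceError(f"screening Cs={cs} must exceed background Cb={cb}")
    if m_soil <= 0:
        raise ValueError("soil mass M must be > 0")
    qi = 1e-6 * m_soil * (cs - ci)
    qib = 1e-6 * m_soil * (cs - cb)
    return qi, qib, qi / qib


def _range_normalize(col: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant column maps to 0.5 (convention)."""
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.full_like(col, 0.5, dtype=float)
    return (col - lo) / (hi - lo)


def integrate_pi(pi_matrix: np.ndarray) -> np.ndarray:
    """Integrated capacity index per site from an n x m per-metal Pi matrix.

    Each metal's Pi is range-normalized over the survey, then combined per
    site with the min-emphasizing Nemerow form sqrt((mean^2 + min^2)/2),
    weighting the metal with the least residual capacity.
    """
    pi_matrix = np.asarray(pi_matrix, dtype=float)
    if pi_matrix.ndim != 2 or pi_matrix.shape[1] == 0:
        raise ValueError("pi_matrix must be n x m with m >= 1")
    norm = np.column_stack([_range_normalize(pi_matrix[:, j])
                            for j in range(pi_matrix.shape[1])])
    return np.sqrt((norm.mean(axis=1) ** 2 + norm.min(axis=1) ** 2) / 2.0)


def classify_risk(pi: float, config: PipelineConfig | None = None) -> str:
    """Risk class label from the capacity index (closed lower bounds)."""
    cfg = config or PipelineConfig()
    for edge, label in cfg.pi_class_bins:
        if pi >= edge:
            return label
    return cfg.pi_overloaded_label


def compute_index_table(survey: SoilSurvey,
                        references: Mapping[str, MetalReference] | None = None,
                        config: PipelineConfig | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All indices for a survey.

    Returns ``(long, per_site)``: a long-format table with one row per
    (site, metal) carrying cf, er, npi, qi, qib, pi and the contamination
    flag (Pi below the configured threshold, equivalently Ci > Cb under the
    default threshold of 1), and a per-site table with the integrated
    Nemerow index, integrated capacity index and risk class.
    """
    refs = references or default_references()
    cfg = config or PipelineConfig()
    rows = []
    for s in survey.samples:
        for m in survey.metals:
            r = refs[m]
            cf = contamination_factor(s.conc[m], r.background_cb)
            qi, qib, pi = capacity_pi(s.conc[m], r.screening_cs,
                                      r.background_cb, cfg.soil_mass_m)
            rows.append({
                "site": s.site_id, "land_use": s.land_use, "metal": m,
                "conc": s.conc[m],
                "cf": cf,
                "er": ecological_risk(r.toxic_response_tr, cf),
                "npi": nemerow_single(s.conc[m], r.standard_limit_sj),
                "qi": qi, "qib": qib, "pi": pi,
                "contaminated": pi < cfg.contamination_pi_threshold,
            })
    long = pd.DataFrame(rows)

    pi_matrix = long.pivot(index="site", columns="metal", values="pi") \
        .reindex(index=survey.site_ids, columns=list(survey.metals)).to_numpy()
    npi_matrix = long.pivot(index="site", columns="metal", values="npi") \
        .reindex(index=survey.site_ids, columns=list(survey.metals)).to_numpy()
    integrated = integrate_pi(pi_matrix)
    per_site = pd.DataFrame({
        "site": survey.site_ids,
        "land_use": survey.land_use,
        "nemerow_integrated": [nemerow_integrated(row) for row in npi_matrix],
        "integrated_pi": integrated,
        "risk_class": [classify_risk(v, cfg) for v in integrated],
    })
    return long, per_site


def class_shares(per_site: pd.DataFrame) -> pd.DataFrame:
    """Percent of sites per risk class (e.g. safe / precautionary / ...)."""
    counts = per_site["risk_class"].value_counts()
    return pd.DataFrame({
        "risk_class": counts.index,
        "share_pct": 100.0 * counts.to_numpy() / len(per_site),
    })
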
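"""Paired photon/proton survival-experiment tables.

One record is a *paired experiment*: the same cell line measured with a
reference photon beam and with protons of a known dose-weighted LET
(LET_d, keV/um), each summarized by fitted LQ parameters.  This is the
structure of compilations such as the PIDE database.  The module reads and
writes a flat CSV dialect, applies the standard data-quality exclusion
rules, computes the iso-survival radiosensitivity metrics, and quantifies
the photon-proton endpoint correlation within LET groups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import lqm
from .lqm import EndpointValue, LQParams

__all__ = [
    "PairedExperiment",
    "FilterReport",
    "FilterConfig",
    "SF_LEVELS",
    "read_survival_table",
    "write_survival_table",
    "apply_exclusion_filters",
    "radiosensitivity_metrics",
    "correlation_by_let",
]

#: The six canonical radiosensitivity metrics: five iso-survival doses and
#: the surviving fraction after 2 Gy.
SF_LEVELS: tuple[float | str, ...] = (0.05, 0.10, 0.20, 0.37, 0.50, "SF_2Gy")

MANDATORY_COLUMNS = [
    "cell_line",
    "alpha_x",
    "beta_x",
    "alpha_p",
    "beta_p",
    "let_d_kev_um",
    "photon_source",
    "assay",
    "oxygenation",
    "source_tag",
]
COV_COLUMNS = ["cov_x_aa", "cov_x_ab", "cov_x_bb", "cov_p_aa", "cov_p_ab", "cov_p_bb"]


@dataclass(frozen=True)
class PairedExperiment:
    """Photon and proton LQ parameters for one cell line / LET combination."""

    cell_line: str
    photon: LQParams
    proton: LQParams
    let_d: float
    photon_source: str = "6 MV"
    assay: str = "clonogenic"
    oxygenation: str = "normoxic"
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.let_d > 0:
            raise ValueError("let_d must be positive")


@dataclass
class FilterReport:
    """Bookkeeping for one pass of the exclusion filters.

    A record failing several rules is counted once per rule but excluded
    once, so ``total_out + (number of uniquely excluded records) == total_in``.
    """

    total_in: int
    excluded_by_rule: dict[str, int]
    total_out: int
    n_excluded_unique: int

    def reconciles(self) -> bool:
        return self.total_out + self.n_excluded_unique == self.total_in


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the data-quality exclusion rules.

    Defaults are the published conventions: drop beta <= 0 for either
    quality (divergent integrals and alpha/beta ratios), hypoxic
    irradiations (OER-inflated RBE), extreme radioresistance (D_10% above
    40 Gy, where the LQ extrapolation is untrustworthy), viability (rather
    than clonogenic) assays, proton LET_d strictly above 37.8 keV/um, and
    photon reference sources below 200 kVp nominal energy.
    """

    max_let: float = 37.8
    max_d10: float = 40.0
    min_photon_kvp: float = 200.0
    excluded_cell_lines: tuple[str, ...] = ()


def _lq_from_row(row, prefix: str, line_no: int) -> LQParams:
    a = row[f"alpha_{prefix}"]
    b = row[f"beta_{prefix}"]
    if pd.isna(a) or pd.isna(b):
        raise ValueError(f"row {line_no}: non-numeric alpha_{prefix}/beta_{prefix}")
    cov = None
    cols = [c for c in COV_COLUMNS if c.split("_")[1] == prefix]
    if all(c in row.index and pd.notna(row[c]) for c in cols):
        aa, ab, bb = (float(row[c]) for c in cols)
        cov = np.array([[aa, ab], [ab, bb]])
    return LQParams(alpha=float(a), beta=float(b), cov=cov)


def read_survival_table(path: str | Path) -> list[PairedExperiment]:
    """Read a paired-experiment CSV (UTF-8, comma separated, header row).

    Raises ``ValueError`` naming the offending row for malformed numeric
    fields, and a dialect error if the header is missing mandatory columns
    or mixes naming conventions.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    suspicious = [c for c in df.columns if c in ("α", "alpha", "alpha_xray", "α_x")]
    if suspicious:
        raise ValueError(f"unrecognized header dialect (found {suspicious})")
    numeric = ["alpha_x", "beta_x", "alpha_p", "beta_p", "let_d_kev_um"] + [
        c for c in COV_COLUMNS if c in df.columns
    ]
    for c in numeric:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in column {c!r} at row(s) {[int(i) + 2 for i in bad]}"
            )
        df[c] = coerced
    records = []
    for i, row in df.iterrows():
        line_no = int(i) + 2  # header is line 1
        let = row["let_d_kev_um"]
        if pd.isna(let):
            raise ValueError(f"row {line_no}: missing LET value")
        records.append(
            PairedExperiment(
                cell_line=str(row["cell_line"]),
                photon=_lq_from_row(row, "x", line_no),
                proton=_lq_from_row(row, "p", line_no),
                let_d=float(let),
                photon_source=str(row["photon_source"]),
                assay=str(row["assay"]),
                oxygenation=str(row["oxygenation"]),
                source_tag=str(row["source_tag"]),
            )
        )
    return records


def to_dataframe(records: Iterable[PairedExperiment]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "cell_line": r.cell_line,
            "alpha_x": r.photon.alpha,
            "beta_x": r.photon.beta,
            "alpha_p": r.proton.alpha,
            "beta_p": r.proton.beta,
            "let_d_kev_um": r.let_d,
            "photon_source": r.photon_source,
            "assay": r.assay,
            "oxygenation": r.oxygenation,
            "source_tag": r.source_tag,
        }
        for prefix, lq in (("x", r.photon), ("p", r.proton)):
            if lq.cov is not None:
                row[f"cov_{prefix}_aa"] = lq.cov[0, 0]
                row[f"cov_{prefix}_ab"] = lq.cov[0, 1]
                row[f"cov_{prefix}_bb"] = lq.cov[1, 1]
        rows.append(row)
    return pd.DataFrame(rows)


def write_survival_table(records: Iterable[PairedExperiment], path: str | Path) -> None:
    to_dataframe(records).to_csv(path, index=False)


_KVP_RE = re.compile(r"([\d.]+)\s*kVp", re.IGNORECASE)
_HIGH_ENERGY_RE = re.compile(r"(\bMV\b|Co-?60|Cs-?137)", re.IGNORECASE)


def _photon_source_too_soft(descriptor: str, min_kvp: float) -> bool:
    """True when the reference photon beam is a sub-threshold kVp x-ray source.

    Megavoltage and Co-60/Cs-137 descriptors pass; unparseable descriptors
    are kept (the rule targets known low-energy sources)."""
    m = _KVP_RE.search(descriptor)
    if m:
        return float(m.group(1)) < min_kvp
    return False


def _d10_exceeds(lq: LQParams, limit: float) -> bool:
    try:
        return lqm.dose_for_sf(lq, 0.10) > limit
    except (lqm.DegenerateCurveError, ValueError):
        return False


def apply_exclusion_filters(
    records: Sequence[PairedExperiment], config: FilterConfig = FilterConfig()
) -> tuple[list[PairedExperiment], FilterReport]:
    """Apply the data-quality exclusion rules; total, never raises.

    Rules (a record may fail several; each failure is tallied under its
    rule, the record is dropped once):

    - ``beta_nonpositive``: beta <= 0 in either quality
    - ``hypoxic``: non-normoxic oxygenation
    - ``radioresistant_d10``: photon or proton D_10% > ``config.max_d10`` Gy
      (usable curves only), or the cell line is on the explicit exclusion list
    - ``viability_assay``: survival measured by a viability assay
    - ``high_let``: LET_d strictly above ``config.max_let`` keV/um
    - ``low_energy_photon``: photon source below ``config.min_photon_kvp``
    """
    counts: dict[str, int] = {
        "beta_nonpositive": 0,
        "hypoxic": 0,
        "radioresistant_d10": 0,
        "viability_assay": 0,
        "high_let": 0,
        "low_energy_photon": 0,
    }
    kept: list[PairedExperiment] = []
    n_excluded = 0
    for r in records:
        failed = []
        if r.photon.beta <= 0 or r.proton.beta <= 0:
            failed.append("beta_nonpositive")
        if r.oxygenation.lower() == "hypoxic":
            failed.append("hypoxic")
        if (
            r.cell_line in config.excluded_cell_lines
            or _d10_exceeds(r.photon, config.max_d10)
            or _d10_exceeds(r.proton, config.max_d10)
        ):
            failed.append("radioresistant_d10")
        if r.assay.lower() == "viability":
            failed.append("viability_assay")
        if r.let_d > config.max_let:
            failed.append("high_let")
        if _photon_source_too_soft(r.photon_source, config.min_photon_kvp):
            failed.append("low_energy_photon")
        if failed:
            n_excluded += 1
            for rule in failed:
                counts[rule] += 1
        else:
            kept.append(r)
    report = FilterReport(
        total_in=len(records),
        excluded_by_rule=counts,
        total_out=len(kept),
        n_excluded_unique=n_excluded,
    )
    return kept, report


def radiosensitivity_metrics(
    exp: PairedExperiment, levels: Sequence[float | str] = SF_LEVELS
) -> dict[str, list[EndpointValue]]:
    """The six radiosensitivity metrics per radiation quality.

    D_5%, D_10%, D_20%, D_37%, D_50% (Gy) and SF_2Gy, with delta-method
    standard errors whenever the record carries an (alpha, beta) covariance.
    """
    out: dict[str, list[EndpointValue]] = {}
    for quality, lq in (("photon", exp.photon), ("proton", exp.proton)):
        vals = []
        for lev in levels:
            if lev == "SF_2Gy":
                sf2 = lqm.surviving_fraction(lq, 2.0)
                stderr = None
                if lq.cov is not None:
                    g = np.array([-2.0 * sf2, -4.0 * sf2])  # d/dalpha, d/dbeta of exp(-2a-4b)
                    stderr = float(np.sqrt(max(g @ lq.cov @ g, 0.0)))
                vals.append(EndpointValue("SF_2Gy", sf2, stderr))
            else:
                d = lqm.dose_for_sf(lq, float(lev))
                stderr = (
                    lqm.propagate_endpoint_error(lq, float(lev)) if lq.cov is not None else None
                )
                vals.append(EndpointValue(float(lev), d, stderr))
        out[quality] = vals
    return out


def endpoint_arrays(
    records: Sequence[PairedExperiment], sf_level: float | str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(photon endpoint, proton endpoint, LET_d) arrays for one metric."""
    x, p, lets = [], [], []
    for r in records:
        if sf_level == "SF_2Gy":
            x.append(lqm.surviving_fraction(r.photon, 2.0))
            p.append(lqm.surviving_fraction(r.proton, 2.0))
        else:
            x.append(lqm.dose_for_sf(r.photon, float(sf_level)))
            p.append(lqm.dose_for_sf(r.proton, float(sf_level)))
        lets.append(r.let_d)
    return np.array(x), np.array(p), np.array(lets)


def correlation_by_let(
    records: Sequence[PairedExperiment],
    sf_level: float | str = 0.10,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Per-LET-group Pearson r and OLS slope/intercept of proton vs photon endpoint.

    Fits are unweighted ordinary least squares.  Groups smaller than
    ``min_group_size`` or with zero photon variance raise ``ValueError``.
    """
    x, p, lets = endpoint_arrays(records, sf_level)
    rows = []
    for let in np.unique(lets):
        sel = lets == let
        if sel.sum() < min_group_size:
            raise ValueError(
                f"LET group {let} has {int(sel.sum())} records (< {min_group_size})"
            )
        if np.ptp(x[sel]) == 0:
            raise ValueError(f"LET group {let}: zero variance in photon endpoint")
        if np.ptp(p[sel]) == 0:
            raise ValueError(f"LET group {let}: zero variance in proton endpoint")
        res = stats.linregress(x[sel], p[sel])
        rows.append(
            {
                "let_d": float(let),
                "n": int(sel.sum()),
                "pearson_r": float(res.rvalue),
                "slope": float(res.slope),
                "intercept": float(res.intercept),
            }
        )
    return pd.DataFrame(rows)
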
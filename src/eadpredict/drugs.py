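"""Conductance-block pharmacology: pIC50 tables and the Hill-1 pore block.

A drug is a set of per-channel pIC50 values (log M; absent means the channel
was screened with no measurable effect) plus its maximum effective free
therapeutic plasma concentration, EFTPC_max (nM).  Block is simple
concentration-dependent pore block with Hill coefficient 1:

    g_j = g_j_baseline / (1 + [D] / IC50_j)

All unit conversion happens in :func:`ic50_nM` (IC50 in nM = 10**(9 - pIC50)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .params import SCALABLE_CURRENTS, ModelParameters

logger = logging.getLogger(__name__)

#: channel keys, in drug-table column order.  IKr is the hERG current.
CHANNELS = SCALABLE_CURRENTS  # ("INa", "ICaL", "IKr", "IKs", "IpNa", "Ito", "IK1")

_COLUMN_FOR_CHANNEL = {
    "INa": "pIC50_INa",
    "ICaL": "pIC50_ICaL",
    "IKr": "pIC50_hERG",
    "IKs": "pIC50_IKs",
    "IpNa": "pIC50_IpNa",
    "Ito": "pIC50_Ito",
    "IK1": "pIC50_IK1",
}


@dataclass
class DrugProfile:
    """One compound: per-channel pIC50s (log M), EFTPC_max (nM), risk class."""

    name: str
    pIC50: dict = field(default_factory=dict)  # channel -> log M
    eftpc_nM: float = float("nan")
    risk_category: int | None = None  # 2 (worst) .. 5 (safest)

    def __post_init__(self) -> None:
        for channel, value in self.pIC50.items():
            if channel not in CHANNELS:
                raise ValueError(f"{self.name}: unknown channel {channel!r}")
            if not np.isfinite(value):
                raise ValueError(f"{self.name}: non-finite pIC50 for {channel}")
            if not (2.0 <= value <= 10.0):
                warnings.warn(
                    f"{self.name}: pIC50 {value} for {channel} outside the "
                    "plausible [2, 10] log M range",
                    stacklevel=2,
                )
        if not (self.eftpc_nM > 0 or np.isnan(self.eftpc_nM)):
            raise ValueError(f"{self.name}: EFTPC_max must be positive (nM)")
        if self.risk_category is not None and self.risk_category not in (2, 3, 4, 5):
            raise ValueError(f"{self.name}: risk category must be in 2..5")

    def ic50_nM(self, channel: str) -> float:
        """IC50 in nM for one channel, or +inf if the drug does not block it."""
        if channel not in self.pIC50:
            return float("inf")
        return ic50_nM(self.pIC50[channel])


def ic50_nM(pic50: float) -> float:
    """Convert a pIC50 (log M) to an IC50 in nM.  Single conversion point."""
    return 10.0 ** (9.0 - pic50)


def block_factor(pic50: float, concentration_nM: float, hill: float = 1.0) -> float:
    """Fractional conductance remaining under pore block, in (0, 1].

    ``1 / (1 + ([D]/IC50)**hill)``; 1.0 at zero concentration, 0.5 at
    [D] = IC50.  The Hill coefficient defaults to 1 — experimental slopes
    are too variable to be worth fitting — and overriding it is logged.
    """
    if concentration_nM < 0:
        raise ValueError("concentration must be >= 0")
    if hill != 1.0:
        logger.warning("Hill coefficient %g used instead of the calibrated 1", hill)
    return 1.0 / (1.0 + (concentration_nM / ic50_nM(pic50)) ** hill)


def apply_drug(profile: DrugProfile, concentration_nM: float | None = None) -> ModelParameters:
    """Model parameters with every screened channel scaled by its block factor.

    The default concentration is the drug's EFTPC_max.  Channels without a
    pIC50 are left at scale 1 (screened, no measurable block); the
    inactivation shift is always 0 — disease interventions are layered on
    separately.
    """
    if concentration_nM is None:
        concentration_nM = profile.eftpc_nM
        if not np.isfinite(concentration_nM):
            raise ValueError(f"{profile.name}: no EFTPC_max and no concentration given")
    scales = {}
    for channel in CHANNELS:
        if channel in profile.pIC50:
            scales[f"scale_{channel}"] = block_factor(profile.pIC50[channel], concentration_nM)
    return ModelParameters(**scales)


def _bundled(name: str):
    return resources.files("eadpredict").joinpath("data", name)


def load_drug_table(path: str | Path | None = None) -> list[DrugProfile]:
    """Read a drug table CSV into profiles.

    Columns: ``name``, seven pIC50 columns (blank = channel not blocked),
    ``eftpc_nM`` and optionally ``risk_category``.  With no path, the bundled
    41-compound table is loaded (risk categories merged in from the bundled
    labels file where available).
    """
    labels = {}
    if path is None:
        path = _bundled("drugs_table1.csv")
        labels = load_risk_labels()
    df = pd.read_csv(path, dtype={"name": str})
    if df.empty:
        warnings.warn(f"drug table {path} contains no rows", stacklevel=2)
        return []

    profiles = []
    for idx, row in df.iterrows():
        pic50 = {}
        for channel, column in _COLUMN_FOR_CHANNEL.items():
            if column not in df.columns:
                continue
            raw = row[column]
            if pd.isna(raw) or (isinstance(raw, str) and raw.strip() in ("", "n/a")):
                continue
            try:
                pic50[channel] = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"row {idx} ({row['name']}), column {column}: bad numeric value {raw!r}"
                ) from exc
        try:
            eftpc = float(row["eftpc_nM"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx} ({row['name']}), column eftpc_nM: bad value") from exc
        category = None
        if "risk_category" in df.columns and not pd.isna(row["risk_category"]):
            category = int(row["risk_category"])
        elif row["name"] in labels:
            category = labels[row["name"]]
        profiles.append(
            DrugProfile(name=row["name"], pIC50=pic50, eftpc_nM=eftpc, risk_category=category)
        )
    return profiles


def save_drug_table(profiles: list[DrugProfile], path: str | Path) -> None:
    """Write profiles back to CSV (inverse of :func:`load_drug_table`)."""
    rows = []
    for prof in profiles:
        row = {"name": prof.name}
        for channel, column in _COLUMN_FOR_CHANNEL.items():
            row[column] = prof.pIC50.get(channel, np.nan)
        row["eftpc_nM"] = prof.eftpc_nM
        row["risk_category"] = prof.risk_category
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_risk_labels(path: str | Path | None = None) -> dict:
    """Drug -> clinical TdP risk category (2..5).

    The bundled file distinguishes categories confirmed in the source text
    from defaults filled in from the Redfern/Mirams classification rule; both
    are returned here, the provenance flag stays in the CSV.
    """
    if path is None:
        path = _bundled("risk_labels.csv")
    df = pd.read_csv(path)
    return {str(r["name"]): int(r["risk_category"]) for _, r in df.iterrows()}
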
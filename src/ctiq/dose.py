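"""Dose accounting: CTDIvol / DLP records and DLP-based effective dose.

Effective dose is estimated from the dose-length product with a
region-specific conversion coefficient; for adult chest CT the conventional
value is k = 0.015 mSv/(mGy cm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CHEST_K_FACTOR", "DoseRecord", "effective_dose", "protocol_summary"]

CHEST_K_FACTOR = 0.015  # mSv per mGy*cm, adult chest


def effective_dose(dlp: float, k_factor: float = CHEST_K_FACTOR) -> float:
    """Effective dose (mSv) = k_factor * DLP (mGy cm)."""
    if dlp < 0:
        raise ValueError("DLP must be non-negative")
    if k_factor < 0:
        raise ValueError("k_factor must be non-negative")
    return k_factor * dlp


@dataclass
class DoseRecord:
    patient_id: str
    protocol: str              # e.g. "full_dose" | "uld"
    ctdi_vol: float            # mGy
    dlp: float                 # mGy*cm
    k_factor: float = CHEST_K_FACTOR
    effective_dose: float = None  # mSv, computed from dlp if not given

    def __post_init__(self) -> None:
        if self.ctdi_vol < 0 or self.dlp < 0:
            raise ValueError("dose quantities must be non-negative")
        if self.effective_dose is None:
            self.effective_dose = effective_dose(self.dlp, self.k_factor)
        elif not np.isclose(self.effective_dose, self.k_factor * self.dlp,
                            rtol=1e-9, atol=1e-12):
            raise ValueError("effective_dose inconsistent with k_factor * dlp")


def protocol_summary(records: Sequence[DoseRecord]) -> dict:
    """Per-protocol mean/min/max of CTDIvol, DLP and effective dose, plus the
    ratio of mean effective doses between each pair of protocols (percent).
    """
    if not records:
        raise ValueError("no dose records")
    df = pd.DataFrame([{
        "protocol": r.protocol, "ctdi_vol": r.ctdi_vol, "dlp": r.dlp,
        "effective_dose": r.effective_dose,
    } for r in records])
    stats = df.groupby("protocol").agg(["mean", "min", "max"])
    summary = {"per_protocol": {}, "mean_effective_dose_ratio_pct": {}}
    for proto, row in stats.iterrows():
        summary["per_protocol"][proto] = {
            q: {"mean": float(row[(q, "mean")]), "min": float(row[(q, "min")]),
                "max": float(row[(q, "max")])}
            for q in ("ctdi_vol", "dlp", "effective_dose")
        }
    means = df.groupby("protocol")["effective_dose"].mean()
    for a in means.index:
        for b in means.index:
            if a != b and means[b] > 0:
                summary["mean_effective_dose_ratio_pct"][f"{a}_vs_{b}"] = \
                    float(100.0 * means[a] / means[b])
    return summary
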
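"""Relating accumulation performance to particle surface properties.

The package ships the study's reference table of six particle species —
1.1 µm polystyrene microspheres (PS1.1) and five bacteria (S. agalactiae,
S. epidermidis, S. aureus, E. coli, K. pneumoniae) — with their measured
zeta potentials, accumulation speeds S_accum and areas A_accum.  The
headline relationship is rank-based: particles with greater negative
surface charge |ζ| accumulate faster and over larger areas.

Note on S. agalactiae: it forms scattered clusters rather than one
recognizable swarm, so its printed area is comparable to weak accumulators
while its label is "No"; classification therefore keys on S_accum, not
area.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParticleRecord",
    "load_table1_fixture",
    "zeta_metric_correlation",
    "classify_accumulation",
    "characterization_report",
]

AccumLabel = Literal["No", "Weak", "Strong"]

#: Default S_accum thresholds (1/s) separating No / Weak / Strong — the
#: round values that split the three printed groups of the reference table.
DEFAULT_THRESHOLDS: tuple[float, float] = (0.5, 2.0)


@dataclass(frozen=True)
class ParticleRecord:
    name: str
    accum_label: AccumLabel
    gram: Literal["+", "-", "synthetic"]
    motile: bool
    size_um: str
    shape: str
    zeta_mv: float
    s_accum: float        # 1/s
    a_accum_um2: float

    def __post_init__(self) -> None:
        if self.accum_label not in ("No", "Weak", "Strong"):
            raise ValueError(f"bad accumulation label {self.accum_label!r}")
        if self.gram not in ("+", "-", "synthetic"):
            raise ValueError(f"bad gram label {self.gram!r}")


def load_table1_fixture(path: str | Path | None = None) -> list[ParticleRecord]:
    """Load the packaged reference table (six records, exactly as printed)."""
    if path is None:
        source = resources.files("ptep.data").joinpath("table1.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    records = [
        ParticleRecord(
            name=row["name"], accum_label=row["accum_label"],
            gram=str(row["gram"]), motile=bool(row["motile"]),
            size_um=str(row["size_um"]), shape=row["shape"],
            zeta_mv=float(row["zeta_mV"]),
            s_accum=float(row["Saccum_per_s"]),
            a_accum_um2=float(row["Aaccum_um2"]))
        for _, row in df.iterrows()]
    return records


def zeta_metric_correlation(records: Sequence[ParticleRecord],
                            metric: Literal["Saccum", "Aaccum"] = "Saccum",
                            ) -> float:
    """Spearman rank correlation between |ζ| and an accumulation metric.

    Rank-based, hence invariant under strictly monotone transforms of
    either variable; ties are mid-ranked.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    zeta = np.array([abs(r.zeta_mv) for r in records])
    if metric == "Saccum":
        y = np.array([r.s_accum for r in records])
    elif metric == "Aaccum":
        y = np.array([r.a_accum_um2 for r in records])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if np.ptp(y) == 0:
        raise ValueError("metric is constant; correlation undefined")
    rho = stats.spearmanr(zeta, y).statistic
    return float(rho)


def classify_accumulation(s_accum: float,
                          thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
                          ) -> AccumLabel:
    """Map an accumulation speed to the No / Weak / Strong label.

    The default thresholds (0.5, 2.0 s⁻¹) are a calibration that separates
    the three groups of the reference table, not a rule from first
    principles.
    """
    weak, strong = thresholds
    if not weak < strong:
        raise ValueError("thresholds must satisfy weak < strong")
    if s_accum < weak:
        return "No"
    if s_accum < strong:
        return "Weak"
    return "Strong"


def characterization_report(records: Sequence[ParticleRecord]) -> dict:
    """JSON-ready synthesis: per-record classification against the printed
    label plus both rank correlations."""
    rows = []
    for r in records:
        predicted = classify_accumulation(r.s_accum)
        rows.append({**asdict(r), "predicted_label": predicted,
                     "label_match": predicted == r.accum_label})
    return {
        "records": rows,
        "label_accuracy": float(np.mean([x["label_match"] for x in rows])),
        "spearman_zeta_saccum": zeta_metric_correlation(records, "Saccum"),
        "spearman_zeta_aaccum": zeta_metric_correlation(records, "Aaccum"),
    }
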
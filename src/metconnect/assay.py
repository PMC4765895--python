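"""MTT dose-response summarisation.

Inhibition of a drug-treated well relative to vehicle (DMSO) and blank wells::

    inhibition = 1 - (OD_compound - OD_blank) / (OD_DMSO - OD_blank)

so 0 means no inhibition (compound OD equals vehicle OD), 1 means complete
inhibition (compound OD equals blank OD), and negative values mean growth
promotion.  Inhibition is computed per replicate and then averaged per
concentration, which also yields the replicate spread for error bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponse",
    "inhibition_rate",
    "summarize_dose_response",
    "read_readings",
    "write_summary",
]


def inhibition_rate(od_compound, od_dmso: float, od_blank: float):
    """Inhibition of a treated well relative to vehicle and blank ODs.

    ``od_compound`` may be a scalar or an array of replicate readings.
    """
    denom = od_dmso - od_blank
    if denom == 0:
        raise ZeroDivisionError("od_dmso equals od_blank; inhibition undefined")
    value = 1.0 - (np.asarray(od_compound, dtype=float) - od_blank) / denom
    return float(value) if value.ndim == 0 else value


@dataclass
class DoseResponse:
    """Replicate OD readings for one drug on one cell line across concentrations.

    ``od_compound`` maps each concentration (mg/mL) to its replicate readings;
    ``od_dmso`` holds the vehicle-control replicates and ``od_blank`` the blank
    OD for the plate.
    """

    drug_id: str
    cell_line: str
    od_compound: dict[float, list[float]]
    od_dmso: list[float]
    od_blank: float

    def __post_init__(self) -> None:
        self.od_compound = {
            float(c): [float(v) for v in reps] for c, reps in self.od_compound.items()
        }
        self.od_dmso = [float(v) for v in self.od_dmso]
        if not self.od_compound:
            raise ValueError(f"{self.drug_id}/{self.cell_line}: no concentrations")
        for c, reps in self.od_compound.items():
            if not reps:
                raise ValueError(
                    f"{self.drug_id}/{self.cell_line}: no replicates at {c} mg/mL"
                )
        if not self.od_dmso:
            raise ValueError(f"{self.drug_id}/{self.cell_line}: no DMSO control readings")
        if float(np.mean(self.od_dmso)) == float(self.od_blank):
            raise ValueError(
                f"{self.drug_id}/{self.cell_line}: DMSO mean equals blank OD"
            )

    @property
    def concentrations(self) -> list[float]:
        return sorted(self.od_compound)


def summarize_dose_response(dr: DoseResponse) -> pd.DataFrame:
    """Per-concentration mean and sample SD of replicate inhibition rates.

    Rows are ordered by increasing concentration; a single replicate reports
    SD 0 with a warning.
    """
    dmso = float(np.mean(dr.od_dmso))
    rows = []
    for conc in dr.concentrations:
        rates = inhibition_rate(np.array(dr.od_compound[conc]), dmso, dr.od_blank)
        rates = np.atleast_1d(rates)
        if rates.size == 1:
            warnings.warn(
                f"{dr.drug_id}/{dr.cell_line}: single replicate at {conc} mg/mL; SD set to 0",
                UserWarning,
                stacklevel=2,
            )
            sd = 0.0
        else:
            sd = float(rates.std(ddof=1))
        rows.append((dr.drug_id, dr.cell_line, conc, float(rates.mean()), sd, rates.size))
    return pd.DataFrame(
        rows,
        columns=[
            "drug_id",
            "cell_line",
            "concentration",
            "mean_inhibition",
            "sd_inhibition",
            "n_replicates",
        ],
    )


DMSO_LABEL = "DMSO"
BLANK_LABEL = "BLANK"


def read_readings(path) -> list[DoseResponse]:
    """Readings TSV: drug, cell_line, concentration, replicate, od.

    Rows with drug ``DMSO`` are vehicle controls and rows with drug ``BLANK``
    are blanks; both are matched to compounds per cell line, with a global
    fallback when a cell line has no blank rows of its own.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"drug", "cell_line", "concentration", "replicate", "od"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    df["drug"] = df["drug"].astype(str)
    df["cell_line"] = df["cell_line"].astype(str)

    dmso = df[df["drug"] == DMSO_LABEL]
    blank = df[df["drug"] == BLANK_LABEL]
    compounds = df[~df["drug"].isin([DMSO_LABEL, BLANK_LABEL])]
    if blank.empty:
        raise ValueError(f"{path}: no {BLANK_LABEL} rows")
    global_blank = float(blank["od"].mean())

    out = []
    for (drug, cell), grp in compounds.groupby(["drug", "cell_line"], sort=True):
        dmso_cell = dmso[dmso["cell_line"] == cell]
        if dmso_cell.empty:
            raise ValueError(f"{path}: no {DMSO_LABEL} rows for cell line {cell!r}")
        blank_cell = blank[blank["cell_line"] == cell]
        od_blank = float(blank_cell["od"].mean()) if not blank_cell.empty else global_blank
        od_compound = {
            float(conc): sub["od"].astype(float).tolist()
            for conc, sub in grp.groupby("concentration", sort=True)
        }
        out.append(
            DoseResponse(
                drug_id=drug,
                cell_line=cell,
                od_compound=od_compound,
                od_dmso=dmso_cell["od"].astype(float).tolist(),
                od_blank=od_blank,
            )
        )
    return out


def write_summary(summaries: list[pd.DataFrame], path) -> None:
    pd.concat(summaries, ignore_index=True).to_csv(path, sep="\t", index=False)
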
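"""Cellular phenotype metrics.

Two read-outs quantify retron function in cells:

* toxin neutralization from OD600 growth data: the full-operon induced /
  uninduced OD600 ratio over the accessory-alone induced/uninduced ratio
  (1 = no rescue; larger = stronger neutralization of accessory toxicity);
* phage-defense sensitivity from plaque counts: plaque-forming units (PFU)
  per mL on the full-operon strain over PFU/mL on the ncRNA/RT-only strain
  (1 = no retron-based defense, 0 = total defense).

Metrics are computed per paired biological replicate and summarized by
mean +/- SD, never by pooling before ratio-taking (ratio-of-means bias).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UndefinedRatioError, ValidationError

OD_COLUMNS = {"strain", "construct", "induced", "replicate", "od600"}
PLAQUE_COLUMNS = {"strain", "construct", "phage", "replicate", "plaque_count",
                  "lysate_volume_ul", "dilution_factor"}


def neutralization_ratio(od_full_ind: float, od_full_unind: float,
                         od_acc_ind: float, od_acc_unind: float) -> float:
    """(full induced/uninduced OD600) / (accessory induced/uninduced OD600)."""
    for name, val in (("od_full_unind", od_full_unind),
                      ("od_acc_unind", od_acc_unind),
                      ("od_acc_ind", od_acc_ind)):
        if val <= 0:
            raise UndefinedRatioError(
                f"neutralization ratio undefined: {name}={val} (must be > 0)"
            )
    if od_full_ind < 0:
        raise ValidationError(f"negative OD600: {od_full_ind}")
    return (od_full_ind / od_full_unind) / (od_acc_ind / od_acc_unind)


def pfu_per_ml(plaque_count: int, lysate_volume_ul: float,
               dilution_factor: float) -> float:
    """Convert a plaque count into PFU per mL of undiluted lysate.

    ``dilution_factor`` is the fraction of the original lysate plated (e.g.
    1e-6 for a million-fold dilution).
    """
    if lysate_volume_ul <= 0:
        raise ValidationError(f"lysate volume must be > 0, got {lysate_volume_ul}")
    if dilution_factor <= 0:
        raise ValidationError(f"dilution factor must be > 0, got {dilution_factor}")
    if plaque_count < 0:
        raise ValidationError(f"negative plaque count: {plaque_count}")
    return plaque_count / (lysate_volume_ul / 1000.0 * dilution_factor)


def sensitivity(pfu_full_operon: float, pfu_ncrna_rt: float) -> float:
    """PFU/mL on the full-operon strain over PFU/mL on the ncRNA/RT strain.

    1 means no retron-based defense; 0 means total defense. Values above 1
    (more plaques with the full operon) are reported as-is.
    """
    if pfu_ncrna_rt <= 0:
        raise UndefinedRatioError(
            f"sensitivity undefined: control PFU/mL is {pfu_ncrna_rt}"
        )
    if pfu_full_operon < 0:
        raise ValidationError(f"negative PFU/mL: {pfu_full_operon}")
    return pfu_full_operon / pfu_ncrna_rt


# ---------------------------------------------------------------------------
# tidy-table interfaces
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: set[str], what: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{what}: missing column(s) {sorted(missing)}"
        )


def neutralization_table(od: pd.DataFrame,
                         full_construct: str = "full-operon",
                         accessory_construct: str = "accessory-only",
                         ) -> pd.DataFrame:
    """Per-replicate neutralization ratios from a tidy OD600 table.

    The table needs columns strain, construct, induced (bool), replicate,
    od600; each (strain, replicate) must supply all four construct/induction
    combinations.
    """
    _require_columns(od, OD_COLUMNS, "OD table")
    rows = []
    for (strain, rep), grp in od.groupby(["strain", "replicate"]):
        def pick(construct: str, induced: bool) -> float:
            sel = grp[(grp["construct"] == construct) & (grp["induced"] == induced)]
            if len(sel) != 1:
                raise ValidationError(
                    f"OD table: strain={strain!r} replicate={rep} needs exactly "
                    f"one row with construct={construct!r}, induced={induced} "
                    f"(got {len(sel)})"
                )
            return float(sel["od600"].iloc[0])

        rows.append({
            "strain": strain,
            "replicate": rep,
            "neutralization_ratio": neutralization_ratio(
                pick(full_construct, True), pick(full_construct, False),
                pick(accessory_construct, True), pick(accessory_construct, False),
            ),
        })
    return pd.DataFrame(rows)


def sensitivity_table(plaques: pd.DataFrame,
                      full_construct: str = "full-operon",
                      control_construct: str = "ncrna-rt") -> pd.DataFrame:
    """Per-replicate phage sensitivity from a tidy plaque-count table."""
    _require_columns(plaques, PLAQUE_COLUMNS, "plaque table")
    df = plaques.copy()
    df["pfu_per_ml"] = [
        pfu_per_ml(int(r.plaque_count), float(r.lysate_volume_ul),
                   float(r.dilution_factor))
        for r in df.itertuples()
    ]
    rows = []
    for (strain, phage, rep), grp in df.groupby(["strain", "phage", "replicate"]):
        def pick(construct: str) -> float:
            sel = grp[grp["construct"] == construct]
            if len(sel) != 1:
                raise ValidationError(
                    f"plaque table: strain={strain!r} phage={phage!r} "
                    f"replicate={rep} needs exactly one {construct!r} row "
                    f"(got {len(sel)})"
                )
            return float(sel["pfu_per_ml"].iloc[0])

        rows.append({
            "strain": strain,
            "phage": phage,
            "replicate": rep,
            "pfu_full_operon": pick(full_construct),
            "pfu_ncrna_rt": pick(control_construct),
            "sensitivity": sensitivity(pick(full_construct),
                                       pick(control_construct)),
        })
    return pd.DataFrame(rows)


def summarize_metric(per_replicate: pd.DataFrame, metric: str,
                     by: list[str]) -> pd.DataFrame:
    """Mean +/- SD (and standard error) of a per-replicate metric."""
    def agg(grp: pd.Series) -> pd.Series:
        vals = grp.to_numpy(dtype=float)
        return pd.Series({
            "mean": vals.mean(),
            "sd": vals.std(ddof=1) if vals.size > 1 else math.nan,
            "sem": (vals.std(ddof=1) / np.sqrt(vals.size)
                    if vals.size > 1 else math.nan),
            "n": vals.size,
        })

    return (per_replicate.groupby(by)[metric].apply(agg).unstack()
            .reset_index())


def write_metric_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
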
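"""qRT-PCR Mean Normalized Expression (MNE) from threshold-cycle tables.

Target abundance relative to a constant reference gene (here typically 18S
rRNA) is computed from threshold cycles and amplification efficiencies as

    MNE = E_ref ** mean(Ct_ref) / E_target ** mean(Ct_target),

with technical replicates averaged on the Ct scale first (the default; a
switch averages per-replicate MNE instead).  E = 2 means perfect per-cycle
doubling.  Biological replicates (n = 3 animals per stage) are summarized
as mean and sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MNEResult", "mne", "stage_mne", "read_ct_table", "run_mne_analysis"]


@dataclass(frozen=True)
class MNEResult:
    """Per gene x stage: MNE mean over animals and its dispersion (1 s.d.)."""

    table: pd.DataFrame  # columns: gene, stage, mne, sd, n


def _check_efficiency(e: float, name: str) -> None:
    if not (1.0 < e <= 2.0):
        raise ValueError(f"{name} amplification efficiency must be in (1, 2], got {e}")


def mne(
    target_cts,
    reference_cts,
    e_target: float = 2.0,
    e_ref: float = 2.0,
    average: str = "ct",
) -> float:
    """MNE for one biological sample from technical-replicate Cts.

    ``average='ct'`` (default) averages technical replicates on the Ct scale
    before exponentiation; ``average='mne'`` averages per-replicate ratios
    (requires equal replicate counts).
    """
    _check_efficiency(e_target, "target")
    _check_efficiency(e_ref, "reference")
    t = np.asarray(list(target_cts), dtype=float)
    r = np.asarray(list(reference_cts), dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("need at least one technical replicate of each gene")
    if (t <= 0).any() or (r <= 0).any():
        raise ValueError("threshold cycles must be positive")
    if average == "ct":
        return float(e_ref ** r.mean() / e_target ** t.mean())
    if average == "mne":
        if t.size != r.size:
            raise ValueError("per-replicate averaging needs paired Cts")
        return float(np.mean(e_ref**r / e_target**t))
    raise ValueError(f"unknown averaging mode {average!r}")


def stage_mne(replicate_mnes) -> tuple[float, float | None]:
    """Mean and sample s.d. of MNE across biological replicates.

    A single replicate returns (value, None): no dispersion is available.
    """
    vals = np.asarray(list(replicate_mnes), dtype=float)
    if vals.size == 0:
        raise ValueError("no biological replicates")
    if vals.size == 1:
        return float(vals[0]), None
    return float(vals.mean()), float(vals.std(ddof=1))


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct CSV with columns gene, sample, stage, replicate, ct[, efficiency]."""
    table = pd.read_csv(path)
    required = {"gene", "sample", "stage", "replicate", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if "efficiency" not in table.columns:
        table["efficiency"] = 2.0
    return table


def run_mne_analysis(
    ct_table: pd.DataFrame, reference: str = "18S", average: str = "ct"
) -> MNEResult:
    """MNE per gene x stage from a long Ct table.

    Every biological sample must carry the reference gene; technical
    replicates are rows sharing (gene, sample).
    """
    genes = [g for g in ct_table["gene"].unique() if g != reference]
    ref_rows = ct_table[ct_table["gene"] == reference]
    if ref_rows.empty:
        raise ValueError(f"reference gene {reference!r} absent from the table")
    ref_by_sample = ref_rows.groupby("sample")

    rows = []
    for gene in genes:
        sub = ct_table[ct_table["gene"] == gene]
        e_target = float(sub["efficiency"].iloc[0])
        per_sample = {}
        for sample, block in sub.groupby("sample"):
            if sample not in ref_by_sample.groups:
                raise ValueError(f"sample {sample!r} lacks reference Cts")
            ref_block = ref_by_sample.get_group(sample)
            per_sample[sample] = (
                mne(
                    block["ct"],
                    ref_block["ct"],
                    e_target=e_target,
                    e_ref=float(ref_block["efficiency"].iloc[0]),
                    average=average,
                ),
                block["stage"].iloc[0],
            )
        by_stage: dict[str, list[float]] = {}
        for value, stage in per_sample.values():
            by_stage.setdefault(stage, []).append(value)
        for stage, vals in by_stage.items():
            m, sd = stage_mne(vals)
            rows.append(
                {"gene": gene, "stage": stage, "mne": m, "sd": sd, "n": len(vals)}
            )
    return MNEResult(table=pd.DataFrame(rows))
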
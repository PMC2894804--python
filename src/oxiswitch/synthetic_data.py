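"""Synthetic probe-level time-course microarray experiments with planted truth.

The generator emulates a five-stage (80/100/120/150/230 d of development),
three-replicate Affymetrix-style experiment on a virtual chip of PM/MM probe
pairs.  Each probe set follows a planted four-letter trajectory code over
{F, U, D} (flat / up / down between adjacent stages), so every downstream
stage of the pipeline — probe-set summarization, moderated testing, consensus
filtering and trajectory clustering — can be checked against known truth.

Intensity model (all on the raw scale, per probe i of gene g on array j):

    PM_ij = O_ij + NSB_ij + s_gj * phi_i * eps_ij
    MM_ij = O_ij + NSB_ij + crosstalk * s_gj * phi_i * eps'_ij

with additive optical background O, lognormal GC-dependent nonspecific
binding NSB (shared within a PM/MM pair), lognormal probe affinity phi
(shared within a pair), multiplicative lognormal measurement noise eps of
unit mean, and specific signal s_gj whose log2 follows the planted
trajectory.  This is the minimal model under which the MAS5, RMA and GCRMA
background corrections each have real work to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ChipLayout",
    "SimulationConfig",
    "TruthTable",
    "ProbeIntensityMatrix",
    "DEFAULT_STAGES",
    "DEFAULT_CODE_FREQUENCIES",
    "build_chip_layout",
    "simulate_truth",
    "simulate_intensities",
    "simulate_experiment",
    "write_experiment",
    "read_experiment",
    "with_zero_noise",
]

DEFAULT_STAGES: tuple[str, ...] = ("80d", "100d", "120d", "150d", "230d")

#: Default planted trajectory mix: ~18% of genes change somewhere, dominated by
#: the late-fetal -> postnatal switch interval, the rest flat.  Up and down
#: movements are balanced within each interval: the global normalizations the
#: pipeline exercises (trimmed-mean scaling, quantile matching) assume
#: globally balanced differential expression, and an unbalanced mix shifts
#: every flat gene at the affected stage.
DEFAULT_CODE_FREQUENCIES: dict[str, float] = {
    "FFFF": 0.82,
    "FFUF": 0.07,
    "FFDF": 0.07,
    "FFFU": 0.02,
    "FFFD": 0.02,
}


@dataclass(frozen=True)
class ChipLayout:
    """Virtual chip geometry: probe sets of PM/MM pairs scattered on a grid.

    ``probes`` has one row per physical probe cell with columns
    ``probe_id, probeset_id, pair_index, is_pm, x, y, gc``.  Rows are ordered
    PM block first, then the matching MM block in the same pair order, so the
    first half and second half of any intensity matrix built on this layout
    are aligned PM/MM partners.
    """

    probe_set_ids: tuple[str, ...]
    probes_per_set: int
    grid: tuple[int, int]  # (rows, cols) of probe cells
    probes: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return len(self.probe_set_ids) * self.probes_per_set

    def pm_mm_view(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """PM rows and MM rows, pair-aligned."""
        n = self.n_pairs
        return self.probes.iloc[:n], self.probes.iloc[n:]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the profiled experiment: five developmental stages with
    three animals each, 11-probe-pair sets, and a trajectory mix dominated by
    the birth-interval switch.  Noise defaults are set so that roughly
    60-70% of probe sets earn a MAS5 Present call and planted log2 fold
    changes of ~2 or more are comfortably detectable with n = 3.
    """

    n_probesets: int = 15_000
    probes_per_set: int = 11
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates: int = 3
    code_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CODE_FREQUENCIES)
    )
    effect_log2_mean: float = 2.5
    effect_log2_sd: float = 0.4
    effect_log2_min: float = 2.0
    base_log2_mean: float = 6.5
    base_log2_sd: float = 1.5
    expressed_fraction: float = 0.55  # of flat genes; changing genes are expressed
    unexpressed_log2_mean: float = -2.0
    unexpressed_log2_sd: float = 1.0
    optical_mean: float = 40.0
    optical_sd: float = 4.0
    nsb_log_mean: float = math.log(30.0)
    nsb_log_sd: float = 0.35
    gc_affinity_coef: float = 0.08  # natural-log NSB increase per GC base
    probe_effect_sd: float = 0.3  # natural-log sd of lognormal phi
    biological_log2_sd: float = 0.25  # animal-to-animal expression variability
    measurement_cv: float = 0.15
    crosstalk: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.code_frequencies.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"code frequencies must sum to 1, got {total}")
        n_intervals = len(self.stages) - 1
        for code in self.code_frequencies:
            if len(code) != n_intervals or set(code) - set("FUD"):
                raise ValueError(f"invalid trajectory code {code!r}")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per stage are required")
        for name in (
            "effect_log2_sd",
            "base_log2_sd",
            "optical_sd",
            "nsb_log_sd",
            "probe_effect_sd",
            "biological_log2_sd",
            "measurement_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_intervals(self) -> int:
        return len(self.stages) - 1

    @property
    def n_arrays(self) -> int:
        return len(self.stages) * self.replicates


@dataclass(frozen=True)
class TruthTable:
    """Planted truth: trajectory code and per-interval log2 effects per gene.

    ``codes`` maps probeset id -> four-letter code; ``effects`` is a
    probeset x interval DataFrame of true log2 fold changes (0 where the
    letter is F, positive for U, negative for D).
    """

    codes: pd.Series
    effects: pd.DataFrame

    def __post_init__(self) -> None:
        flat = self.effects.to_numpy() == 0.0
        letters = np.array([list(c) for c in self.codes.to_numpy()])
        if not np.array_equal(letters == "F", flat):
            raise ValueError("code letters inconsistent with zero/nonzero effects")


@dataclass(frozen=True)
class ProbeIntensityMatrix:
    """Raw probe x array intensities plus sample sheet and chip layout."""

    intensities: pd.DataFrame  # probe_id-indexed, one column per array
    samples: pd.DataFrame  # array_id, stage, replicate
    layout: ChipLayout

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() <= 0).any():
            raise ValueError("all raw intensities must be positive")
        if list(self.intensities.index) != list(self.layout.probes["probe_id"]):
            raise ValueError("intensity rows must cover the layout's probes in order")
        if list(self.intensities.columns) != list(self.samples["array_id"]):
            raise ValueError("intensity columns must match the sample sheet")

    @property
    def array_ids(self) -> list[str]:
        return list(self.samples["array_id"])

    def pm_mm_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Intensities reshaped to (n_probesets, probes_per_set, n_arrays)."""
        lay = self.layout
        vals = self.intensities.to_numpy(dtype=float)
        n_sets = len(lay.probe_set_ids)
        shape = (n_sets, lay.probes_per_set, vals.shape[1])
        pm = vals[: lay.n_pairs].reshape(shape)
        mm = vals[lay.n_pairs :].reshape(shape)
        return pm, mm


def build_chip_layout(
    n_probesets: int, probes_per_set: int = 11, seed: int = 0
) -> ChipLayout:
    """Lay out ``n_probesets`` sets of PM/MM pairs scattered over a square-ish grid.

    Each PM probe sits at (x, y) with its MM partner directly below at
    (x, y+1), as on physical chips; the pairs of one probe set are scattered
    across the grid rather than contiguous.  GC content of each 25-mer pair
    is drawn binomially.  Deterministic for a fixed seed.
    """
    if n_probesets < 1 or probes_per_set < 1:
        raise ValueError("need at least one probe set and one probe per set")
    rng = np.random.default_rng(seed)
    n_pairs = n_probesets * probes_per_set
    cols = int(math.ceil(math.sqrt(2 * n_pairs)))
    pair_rows = int(math.ceil(n_pairs / cols))
    rows = 2 * pair_rows
    if rows * cols < 2 * n_pairs:
        raise ValueError("grid too small for the requested probes")

    slots = rng.permutation(pair_rows * cols)[:n_pairs]
    x = slots % cols
    y_pm = 2 * (slots // cols)
    gc = rng.binomial(25, 0.5, size=n_pairs)

    probe_set_ids = tuple(f"ps{g:05d}" for g in range(n_probesets))
    set_of_pair = np.repeat(np.arange(n_probesets), probes_per_set)
    within = np.tile(np.arange(probes_per_set), n_probesets)
    ps_col = np.array(probe_set_ids)[set_of_pair]

    def block(is_pm: bool) -> pd.DataFrame:
        tag = "pm" if is_pm else "mm"
        return pd.DataFrame(
            {
                "probe_id": [
                    f"{ps}_{k}_{tag}" for ps, k in zip(ps_col, within, strict=True)
                ],
                "probeset_id": ps_col,
                "pair_index": np.arange(n_pairs),
                "is_pm": is_pm,
                "x": x,
                "y": y_pm if is_pm else y_pm + 1,
                "gc": gc,
            }
        )

    probes = pd.concat([block(True), block(False)], ignore_index=True)
    return ChipLayout(
        probe_set_ids=probe_set_ids,
        probes_per_set=probes_per_set,
        grid=(rows, cols),
        probes=probes,
    )


def simulate_truth(config: SimulationConfig) -> TruthTable:
    """Draw each gene's trajectory code and per-interval log2 effects.

    Codes follow ``config.code_frequencies``; nonzero effect magnitudes are
    normal(effect_log2_mean, effect_log2_sd) truncated below at
    ``effect_log2_min``, signed by the letter (U positive, D negative).
    """
    rng = np.random.default_rng(config.seed)
    codes_pool = list(config.code_frequencies)
    probs = np.array([config.code_frequencies[c] for c in codes_pool])
    ids = [f"ps{g:05d}" for g in range(config.n_probesets)]
    codes = rng.choice(codes_pool, size=config.n_probesets, p=probs)

    letters = np.array([list(c) for c in codes])  # (genes, intervals)
    mags = rng.normal(
        config.effect_log2_mean, config.effect_log2_sd, size=letters.shape
    )
    mags = np.maximum(np.abs(mags), config.effect_log2_min)
    effects = np.zeros(letters.shape)
    effects[letters == "U"] = mags[letters == "U"]
    effects[letters == "D"] = -mags[letters == "D"]

    interval_names = [
        f"{a}_vs_{b}" for a, b in zip(config.stages[:-1], config.stages[1:])
    ]
    return TruthTable(
        codes=pd.Series(codes, index=ids, name="code"),
        effects=pd.DataFrame(effects, index=ids, columns=interval_names),
    )


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        (f"{stage}_r{r + 1}", stage, r + 1)
        for stage in config.stages
        for r in range(config.replicates)
    ]
    return pd.DataFrame(rows, columns=["array_id", "stage", "replicate"])


def simulate_intensities(
    layout: ChipLayout, truth: TruthTable, config: SimulationConfig
) -> ProbeIntensityMatrix:
    """Realize raw PM/MM intensities from the planted truth under the noise model."""
    if list(truth.codes.index) != list(layout.probe_set_ids):
        raise ValueError("truth table and chip layout disagree on probe-set ids")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA55A]))
    samples = _sample_sheet(config)
    n_arrays = len(samples)
    n_genes = len(layout.probe_set_ids)
    n_pairs = layout.n_pairs
    k = layout.probes_per_set

    # Specific signal per gene per array: log2 trajectory + planted effects.
    # Flat genes may be unexpressed (background-level signal); a gene with a
    # planted change is necessarily expressed, else the change is unobservable.
    flat_code = "F" * config.n_intervals
    is_flat = truth.codes.to_numpy() == flat_code
    expressed = ~is_flat | (rng.random(n_genes) < config.expressed_fraction)
    base = np.where(
        expressed,
        rng.normal(config.base_log2_mean, config.base_log2_sd, size=n_genes),
        rng.normal(
            config.unexpressed_log2_mean, config.unexpressed_log2_sd, size=n_genes
        ),
    )
    stage_log2 = np.concatenate(
        [np.zeros((n_genes, 1)), np.cumsum(truth.effects.to_numpy(), axis=1)], axis=1
    ) + base[:, None]
    stage_idx = samples["stage"].map(
        {s: i for i, s in enumerate(config.stages)}
    ).to_numpy()
    log2_s = stage_log2[:, stage_idx]
    if config.biological_log2_sd > 0:
        # each array is a different animal: gene-level biological deviation
        log2_s = log2_s + rng.normal(
            0.0, config.biological_log2_sd, size=log2_s.shape
        )
    s = 2.0 ** log2_s  # (genes, arrays)
    s_pair = np.repeat(s, k, axis=0)  # (pairs, arrays)

    pm_meta, _ = layout.pm_mm_view()
    gc = pm_meta["gc"].to_numpy()

    optical = np.maximum(
        rng.normal(config.optical_mean, config.optical_sd, size=(n_pairs, n_arrays)),
        1.0,
    )
    nsb = np.exp(
        config.nsb_log_mean
        + config.gc_affinity_coef * (gc[:, None] - 12.5)
        + rng.normal(0.0, config.nsb_log_sd, size=(n_pairs, n_arrays))
    )
    phi = np.exp(rng.normal(0.0, config.probe_effect_sd, size=n_pairs))[:, None]

    def eps() -> np.ndarray:
        if config.measurement_cv == 0:
            return np.ones((n_pairs, n_arrays))
        sig = math.sqrt(math.log1p(config.measurement_cv**2))
        return np.exp(rng.normal(-0.5 * sig * sig, sig, size=(n_pairs, n_arrays)))

    pm = optical + nsb + s_pair * phi * eps()
    mm = optical + nsb + config.crosstalk * s_pair * phi * eps()

    vals = np.concatenate([pm, mm], axis=0)
    intensities = pd.DataFrame(
        vals, index=layout.probes["probe_id"].to_numpy(), columns=samples["array_id"]
    )
    intensities.index.name = "probe_id"
    return ProbeIntensityMatrix(intensities=intensities, samples=samples, layout=layout)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ChipLayout, TruthTable, ProbeIntensityMatrix]:
    """Convenience wrapper: layout + truth + intensities from one config."""
    layout = build_chip_layout(
        config.n_probesets, config.probes_per_set, seed=config.seed
    )
    truth = simulate_truth(config)
    pim = simulate_intensities(layout, truth, config)
    return layout, truth, pim


# ---------------------------------------------------------------------------
# Plain-text interchange: CEL-like TSV + sample sheet CSV + truth CSV.


def write_experiment(
    pim: ProbeIntensityMatrix, out_dir, truth: TruthTable | None = None
) -> None:
    """Write the CEL-like probe TSV, sample-sheet CSV and (optionally) truth CSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pim.layout.probes[["probe_id", "probeset_id", "is_pm", "x", "y", "gc"]].copy()
    table["is_pm"] = table["is_pm"].astype(int)
    table = pd.concat([table.reset_index(drop=True),
                       pim.intensities.reset_index(drop=True)], axis=1)
    table.to_csv(out / "probes.tsv", sep="\t", index=False, float_format="%.4f")
    pim.samples.to_csv(out / "samples.csv", index=False)
    if truth is not None:
        tt = truth.effects.copy()
        tt.insert(0, "code", truth.codes)
        tt.to_csv(out / "truth.csv", index_label="probeset_id")


def read_experiment(in_dir) -> ProbeIntensityMatrix:
    """Read an experiment written by :func:`write_experiment`."""
    from pathlib import Path

    inp = Path(in_dir)
    table = pd.read_csv(inp / "probes.tsv", sep="\t")
    samples = pd.read_csv(inp / "samples.csv")
    meta_cols = ["probe_id", "probeset_id", "is_pm", "x", "y", "gc"]
    array_cols = [c for c in table.columns if c not in meta_cols]
    if array_cols != list(samples["array_id"]):
        raise ValueError("probe TSV arrays do not match the sample sheet")

    probes = table[meta_cols].copy()
    probes["is_pm"] = probes["is_pm"].astype(bool)
    pm = probes[probes["is_pm"]]
    probe_set_ids = tuple(dict.fromkeys(pm["probeset_id"]))
    counts = pm["probeset_id"].value_counts()
    if counts.nunique() != 1:
        raise ValueError("probe sets must all have the same number of pairs")
    probes["pair_index"] = np.concatenate(
        [np.arange(len(pm)), np.arange(len(probes) - len(pm))]
    )
    layout = ChipLayout(
        probe_set_ids=probe_set_ids,
        probes_per_set=int(counts.iloc[0]),
        grid=(int(probes["y"].max()) + 1, int(probes["x"].max()) + 1),
        probes=probes.reset_index(drop=True),
    )
    intensities = table[array_cols].copy()
    intensities.index = table["probe_id"].to_numpy()
    intensities.index.name = "probe_id"
    return ProbeIntensityMatrix(intensities=intensities, samples=samples, layout=layout)


def with_zero_noise(config: SimulationConfig, crosstalk: float = 0.0) -> SimulationConfig:
    """A copy of ``config`` with every noise source switched off.

    Useful for identity checks: with zero noise and zero crosstalk,
    PM - MM equals the specific signal exactly.
    """
    return replace(
        config,
        optical_sd=0.0,
        nsb_log_sd=0.0,
        probe_effect_sd=0.0,
        biological_log2_sd=0.0,
        measurement_cv=0.0,
        base_log2_sd=0.0,
        unexpressed_log2_sd=0.0,
        expressed_fraction=1.0,
        crosstalk=crosstalk,
    )
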
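"""Consensus filtering and F/U/D trajectory clustering.

A gene x contrast pair is called consensus differentially expressed when

* its convergence — the percentage of the three summarization methods
  (MAS5, RMA, GCRMA) that call it significant at the FDR target — exceeds
  50% (i.e. at least 2 of 3 methods agree), and
* the gene is called Present by MAS5 detection in at least half of all
  arrays in the experiment.

Each consensus gene then receives a four-letter trajectory code over
{F, U, D}: per adjacent-stage interval, F if not consensus-DE, otherwise U
or D by the direction of the MAS5 stage-mean change.  With five stages
(four intervals) and three states the code space holds 3^4 = 81 possible
clusters; only clusters of at least 50 genes are reported by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .probe_summarization import ExpressionSet
from .differential_expression import run_differential_expression

__all__ = [
    "TrajectoryCluster",
    "convergence_percent",
    "convergence_table",
    "consensus_filter",
    "present_counts",
    "assign_code",
    "assign_codes",
    "build_clusters",
    "count_possible_codes",
    "summarize_de",
    "expressed_universe",
    "run_consensus_pipeline",
]


@dataclass(frozen=True)
class TrajectoryCluster:
    """One co-expression cluster: its code, members and reporting flag."""

    code: str
    members: tuple[str, ...]
    reported: bool

    @property
    def size(self) -> int:
        return len(self.members)


def convergence_percent(flags) -> float:
    """Share of the three methods calling the gene significant, to 1 decimal."""
    flags = list(flags)
    if len(flags) != 3:
        raise ValueError("convergence is defined over exactly 3 method flags")
    return round(100.0 * sum(bool(f) for f in flags) / 3.0, 1)


def convergence_table(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per gene x contrast: method flags and convergence percent.

    ``results`` maps method name -> ContrastResult table from
    :func:`~oxiswitch.differential_expression.run_differential_expression`.
    """
    if len(results) != 3:
        raise ValueError("expected results from exactly 3 methods")
    flags = {
        method: res.set_index(["gene", "contrast"])["significant"]
        for method, res in results.items()
    }
    table = pd.DataFrame(flags)
    if table.isna().any().any():
        raise ValueError("methods disagree on the gene x contrast grid")
    table["convergence"] = (100.0 * table.mean(axis=1)).round(1)
    return table.reset_index()


def present_counts(calls: pd.DataFrame) -> pd.Series:
    """Number of arrays in which each gene is called Present."""
    return (calls == "P").sum(axis=1)


def consensus_filter(
    convergence: pd.DataFrame,
    calls: pd.DataFrame,
    min_convergence: float = 50.0,
    count_marginal: bool = False,
) -> pd.DataFrame:
    """Keep gene x contrast pairs with convergence > 50% and Present in >= half of arrays.

    The Present filter is applied per gene over all arrays of the experiment
    (threshold ceil(N/2)); both conditions must hold.  Returns the kept rows
    of ``convergence``.
    """
    n_arrays = calls.shape[1]
    need = math.ceil(n_arrays / 2)
    ok_calls = calls.isin(["P", "M"]) if count_marginal else (calls == "P")
    present_ok = ok_calls.sum(axis=1) >= need
    keep = (convergence["convergence"] > min_convergence) & convergence["gene"].map(
        present_ok
    ).fillna(False)
    return convergence[keep].reset_index(drop=True)


def assign_code(de_flags, mean_deltas) -> str:
    """Four-letter code for one gene: F / U / D per interval.

    ``de_flags`` marks the consensus-DE intervals; ``mean_deltas`` are the
    MAS5 stage-mean changes (later minus earlier).  A consensus-DE interval
    with an exactly zero mean change carries no direction evidence and
    resolves to F.
    """
    letters = []
    for de, delta in zip(de_flags, mean_deltas, strict=True):
        if not de or delta == 0:
            letters.append("F")
        else:
            letters.append("U" if delta > 0 else "D")
    return "".join(letters)


def assign_codes(
    kept: pd.DataFrame, mas5_expr: ExpressionSet, samples: pd.DataFrame
) -> pd.Series:
    """Trajectory codes for every gene that passed the consensus filter.

    Directions come from normalized MAS5 stage-mean intensities only (the
    three methods' intensity scales are not comparable, so a single scale
    defines the shapes).
    """
    sm = mas5_expr.stage_means(samples)
    stages = list(sm.columns)
    intervals = [f"{a}_vs_{b}" for a, b in zip(stages[:-1], stages[1:])]
    deltas = sm.to_numpy()[:, 1:] - sm.to_numpy()[:, :-1]
    delta_df = pd.DataFrame(deltas, index=sm.index, columns=intervals)

    de = (
        kept.assign(flag=True)
        .pivot_table(index="gene", columns="contrast", values="flag", fill_value=False)
        .reindex(columns=intervals, fill_value=False)
    )
    codes = {}
    for gene, row in de.iterrows():
        codes[gene] = assign_code(row.to_numpy(), delta_df.loc[gene].to_numpy())
    return pd.Series(codes, name="code").sort_index()


def build_clusters(codes: pd.Series, min_size: int = 50) -> list[TrajectoryCluster]:
    """Group genes by code; clusters of >= ``min_size`` genes are flagged reported."""
    clusters = []
    for code, members in codes.groupby(codes).groups.items():
        clusters.append(
            TrajectoryCluster(
                code=str(code),
                members=tuple(sorted(members)),
                reported=len(members) >= min_size,
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.code))
    return clusters


def count_possible_codes(n_intervals: int = 4, n_states: int = 3) -> int:
    """Size of the trajectory code space: n_states ** n_intervals (81 for 4 x 3)."""
    if n_intervals < 0 or n_states < 1:
        raise ValueError("need nonnegative intervals and at least one state")
    return n_states**n_intervals


def expressed_universe(calls: pd.DataFrame, samples: pd.DataFrame) -> pd.Index:
    """Genes Present or Marginal in at least one developmental stage.

    A stage-level call requires a majority of that stage's replicates to be
    P or M.
    """
    ok = calls.isin(["P", "M"])
    stage_of = dict(zip(samples["array_id"], samples["stage"]))
    by_stage = ok.T.groupby(ok.columns.map(stage_of), sort=False).mean().T
    return calls.index[(by_stage > 0.5).any(axis=1)]


def summarize_de(
    n_expressed: int, n_de: int, cluster_sizes: dict[str, int] | None = None
) -> dict[str, float]:
    """Reporting percentages: DE share of expressed genes, cluster share of DE.

    ``de_percent`` = 100 * n_de / n_expressed (1 decimal); when cluster sizes
    are given, ``cluster_percent_of_de`` = 100 * sum(sizes) / n_de.
    """
    if n_de > n_expressed:
        raise ValueError("more DE genes than expressed genes")
    out: dict[str, float] = {
        "n_expressed": n_expressed,
        "n_de": n_de,
        "de_percent": round(100.0 * n_de / n_expressed, 1) if n_expressed else 0.0,
    }
    if cluster_sizes is not None:
        total = sum(cluster_sizes.values())
        out["cluster_percent_of_de"] = (
            round(100.0 * total / n_de, 1) if n_de else 0.0
        )
    return out


def run_consensus_pipeline(
    expr_sets: dict[str, ExpressionSet],
    samples: pd.DataFrame,
    fdr: float = 0.01,
    min_cluster_size: int = 50,
) -> dict:
    """Full consensus analysis from three ExpressionSets to reported clusters.

    Returns a dict with the per-method ContrastResult tables, the convergence
    table, the kept gene x contrast pairs, the per-gene codes, the cluster
    list and the summary percentages.
    """
    mas5_expr = expr_sets["MAS5"]
    if mas5_expr.detection_calls is None:
        raise ValueError("MAS5 expression set must carry detection calls")
    results = {
        name: run_differential_expression(es, samples, fdr=fdr)
        for name, es in expr_sets.items()
    }
    conv = convergence_table(results)
    kept = consensus_filter(conv, mas5_expr.detection_calls)
    codes = assign_codes(kept, mas5_expr, samples)
    codes = codes[codes != "F" * (len(mas5_expr.stage_means(samples).columns) - 1)]
    clusters = build_clusters(codes, min_size=min_cluster_size)

    universe = expressed_universe(mas5_expr.detection_calls, samples)
    summary = summarize_de(
        n_expressed=len(universe),
        n_de=len(codes),
        cluster_sizes={c.code: c.size for c in clusters if c.reported},
    )
    return {
        "results": results,
        "convergence": conv,
        "kept": kept,
        "codes": codes,
        "clusters": clusters,
        "summary": summary,
    }
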
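"""Exon-level splicing statistics: skipping percentage, PSI, group comparison.

Works from per-sample isoform percentage tables (the output of the isoform
caller, or any published table of isoform percentages).  For an exon e,

    skip(e) = sum of percentages of isoforms whose pattern excludes e
    PSI(e)  = 100 - skip(e)

computed on unrounded fractions so the two always sum to exactly 100.
Isoforms pooled into "others" lack pattern resolution and are excluded;
a warning is emitted when the others bucket exceeds 5% of reads.

Group comparison uses a two-sided Mann-Whitney U test per exon with
Benjamini-Hochberg adjustment across exons — a rank-based choice suited to
the small sample counts typical of clinical cohorts.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_model import ExonModel, asr_exon_set, parse_pattern
from .isoform_caller import IsoformTable

__all__ = [
    "exon_skip_percent",
    "psi",
    "psi_table",
    "group_summary",
    "compare_groups",
    "load_bladder_table",
]


def _percent_map(table: "IsoformTable | Mapping[str, float]") -> dict[str, float]:
    if isinstance(table, IsoformTable):
        percents = table.percentages
        if table.others_percent > 5.0:
            warnings.warn(
                f"others bucket is {table.others_percent:.1f}% of reads; exon-level "
                "statistics ignore pooled isoforms", stacklevel=3)
        return percents
    return dict(table)


def exon_skip_percent(
    table: "IsoformTable | Mapping[str, float]",
    exon: int,
    model: "ExonModel | Iterable[int]",
) -> float:
    """Percentage of transcripts whose isoform pattern excludes ``exon``.

    ``model`` may be a full :class:`ExonModel` or just the ASR exon numbers.
    """
    asr = asr_exon_set(model)
    if exon not in asr:
        raise ValueError(f"exon {exon} outside ASR {sorted(asr)}")
    total = 0.0
    for name, pct in _percent_map(table).items():
        if exon not in parse_pattern(name, model):
            total += pct
    return total


def psi(
    table: "IsoformTable | Mapping[str, float]",
    exon: int,
    model: "ExonModel | Iterable[int]",
) -> float:
    """Percent spliced-in: complement of the skipping percentage."""
    return 100.0 - exon_skip_percent(table, exon, model)


def psi_table(
    tables: Sequence["IsoformTable | Mapping[str, float]"],
    exons: Sequence[int],
    model: "ExonModel | Iterable[int]",
    sample_ids: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format per-sample, per-exon skip/PSI table."""
    if sample_ids is None:
        sample_ids = [
            t.sample_id if isinstance(t, IsoformTable) else f"sample{i}"
            for i, t in enumerate(tables)
        ]
    rows = []
    for i, table in enumerate(tables):
        for exon in exons:
            skip = exon_skip_percent(table, exon, model)
            rows.append(
                {
                    "sample_id": sample_ids[i],
                    "group": groups[i] if groups is not None else None,
                    "exon": exon,
                    "skip_percent": skip,
                    "psi_percent": 100.0 - skip,
                }
            )
    return pd.DataFrame(rows)


def group_summary(
    tables: Sequence["IsoformTable | Mapping[str, float]"],
    groups: Sequence[str],
    model: "ExonModel | Iterable[int]",
    exons: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-group arithmetic means of isoform percentages and exon PSI.

    Returns one row per group; isoform columns carry the mean percentage of
    each isoform seen in any sample, ``psi_<exon>`` columns the mean PSI.
    Unrounded means are returned (round for display).
    """
    if len(tables) != len(groups):
        raise ValueError("one group label per sample required")
    if not tables:
        raise ValueError("empty group")
    if exons is None:
        asr = sorted(asr_exon_set(model))
        exons = [n for n in asr if n not in (asr[0], asr[-1])]  # interior exons
    all_names: list[str] = []
    for t in tables:
        for name in _percent_map(t):
            if name not in all_names:
                all_names.append(name)
    records = []
    for i, t in enumerate(tables):
        pm = _percent_map(t)
        rec = {"group": groups[i]}
        rec.update({name: pm.get(name, 0.0) for name in all_names})
        rec.update({f"psi_{e}": psi(t, e, model) for e in exons})
        records.append(rec)
    df = pd.DataFrame(records)
    out = df.groupby("group", sort=False).mean()
    if out.isna().any().any():
        raise ValueError("empty group")
    return out


def compare_groups(
    psi_a: Mapping[int, Sequence[float]],
    psi_b: Mapping[int, Sequence[float]],
    min_samples: int = 3,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per exon, BH-adjusted across exons.

    ``psi_a`` / ``psi_b`` map exon number to the per-sample PSI values of
    each group.  Returns exon, statistic, p_value, adjusted_p, significant
    (at 0.05).
    """
    exons = sorted(psi_a)
    if sorted(psi_b) != exons:
        raise ValueError("groups list different exons")
    rows = []
    for exon in exons:
        a, b = list(psi_a[exon]), list(psi_b[exon])
        if len(a) < min_samples or len(b) < min_samples:
            raise ValueError(f"exon {exon}: need >= {min_samples} samples per group")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        rows.append({"exon": exon, "statistic": float(res.statistic),
                     "p_value": float(res.pvalue)})
    df = pd.DataFrame(rows)
    reject, adj, _, _ = multipletests(df["p_value"], alpha=0.05, method="fdr_bh")
    df["adjusted_p"] = adj
    df["significant"] = reject
    return df


def load_bladder_table() -> pd.DataFrame:
    """Published isoform percentages for bladder samples.

    Per-sample isoform percentages from long-read amplicon sequencing of the
    alternative splicing region in five normal bladder epithelia and nine
    muscle-invasive bladder carcinomas.  Columns: ``sample``, ``group``
    (normal/tumor), then one column per Δ-named isoform.
    """
    with resources.files("utxsplice.data").joinpath("bladder_samples.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
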
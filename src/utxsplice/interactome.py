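"""Affinity-purification MS scoring: moderated t-test and iBAQ stoichiometry.

Implements the standard label-free interactomics workflow for GFP pulldowns
versus bead controls:

1.  preprocessing — drop contaminant/reverse/singly-identified protein groups
    and move LFQ intensities to log2 scale, keeping missing values explicit;
2.  imputation — replace missing log2 values per replicate column with draws
    from a down-shifted, narrowed Gaussian fitted to the observed values
    (``shift`` and ``width`` expressed in units of the column's standard
    deviation), modelling intensities below the detection limit;
3.  an S0-moderated two-sample t-test with permutation-based FDR control —
    the statistic ``(mean_GFP - mean_ctrl) / (s0 + pooled SE)`` damps
    low-variance artifacts; significance is calibrated by group-label
    permutations, with a Benjamini-Hochberg fallback on the classical
    parametric p-values when too few distinct permutations exist;
4.  iBAQ stoichiometry — control-subtracted mean iBAQ per protein, clipped at
    zero and normalized to an anchor subunit (default PAXIP1, the MLL3/MLL4
    subunit conventionally used as the reference).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PulldownMatrix",
    "load_pulldown_tsv",
    "write_pulldown_tsv",
    "load_complex_annotation",
    "preprocess",
    "impute",
    "s0_ttest",
    "stoichiometry",
]


@dataclass(frozen=True)
class PulldownMatrix:
    """Protein x replicate intensity matrix with LFQ and iBAQ layers.

    ``lfq`` and ``ibaq`` are DataFrames indexed by protein id with one column
    per replicate; ``groups`` maps group name ("GFP", "control") to its
    replicate column names.  ``flags`` carries per-protein booleans
    ``is_contaminant`` / ``is_reverse`` and the integer
    ``n_replicates_identified``.  ``log2_scale`` records whether the LFQ layer
    has been log2-transformed.  Missing intensities are NaN.
    """

    lfq: pd.DataFrame
    ibaq: pd.DataFrame
    flags: pd.DataFrame
    groups: Mapping[str, Sequence[str]]
    log2_scale: bool = False

    def __post_init__(self) -> None:
        cols = set(self.lfq.columns)
        for g, reps in self.groups.items():
            missing = set(reps) - cols
            if missing:
                raise ValueError(f"group {g!r}: replicate columns {sorted(missing)} absent")
        if not self.lfq.index.equals(self.ibaq.index):
            raise ValueError("LFQ and iBAQ layers index different proteins")

    @property
    def proteins(self) -> pd.Index:
        return self.lfq.index

    def group_columns(self, group: str) -> list[str]:
        return list(self.groups[group])


def load_pulldown_tsv(
    path,
    groups: Mapping[str, Sequence[str]] | None = None,
    lfq_prefix: str = "LFQ intensity ",
    ibaq_prefix: str = "iBAQ ",
) -> PulldownMatrix:
    """Read a MaxQuant-style proteinGroups TSV.

    Expects columns ``Protein IDs``, ``Reverse``, ``Potential contaminant``
    (marked with "+"), and per-replicate ``LFQ intensity <rep>`` / ``iBAQ
    <rep>`` columns.  Zero intensities are treated as missing.  When
    ``groups`` is omitted, replicates whose name starts with "GFP" form the
    GFP group and the rest the control group.
    """
    df = pd.read_csv(path, sep="\t")
    if "Protein IDs" not in df.columns:
        raise ValueError("not a proteinGroups table: missing 'Protein IDs' column")
    df = df.set_index("Protein IDs")
    lfq_cols = [c for c in df.columns if c.startswith(lfq_prefix)]
    ibaq_cols = [c for c in df.columns if c.startswith(ibaq_prefix) and c != "iBAQ"]
    reps = [c[len(lfq_prefix):] for c in lfq_cols]
    lfq = df[lfq_cols].astype(float)
    lfq.columns = reps
    ibaq = df[[f"{ibaq_prefix}{r}" for r in reps if f"{ibaq_prefix}{r}" in ibaq_cols]].astype(float)
    ibaq.columns = [c[len(ibaq_prefix):] for c in ibaq.columns]
    ibaq = ibaq.reindex(columns=reps)
    lfq = lfq.mask(lfq <= 0)
    ibaq = ibaq.mask(ibaq <= 0)
    flags = pd.DataFrame(
        {
            "is_contaminant": df.get("Potential contaminant", "").fillna("") == "+",
            "is_reverse": df.get("Reverse", "").fillna("") == "+",
            "n_replicates_identified": lfq.notna().sum(axis=1),
        },
        index=df.index,
    )
    if groups is None:
        gfp = [r for r in reps if r.upper().startswith("GFP")]
        groups = {"GFP": gfp, "control": [r for r in reps if r not in gfp]}
    return PulldownMatrix(lfq=lfq, ibaq=ibaq, flags=flags, groups=groups)


def write_pulldown_tsv(matrix: PulldownMatrix, path) -> None:
    """Write a matrix back out in MaxQuant proteinGroups layout.

    Missing intensities become 0, matching MaxQuant's convention.
    """
    df = pd.DataFrame(index=matrix.proteins)
    df.index.name = "Protein IDs"
    for col in matrix.lfq.columns:
        df[f"LFQ intensity {col}"] = matrix.lfq[col].fillna(0.0)
    for col in matrix.ibaq.columns:
        df[f"iBAQ {col}"] = matrix.ibaq[col].fillna(0.0)
    df["Reverse"] = np.where(matrix.flags["is_reverse"], "+", "")
    df["Potential contaminant"] = np.where(matrix.flags["is_contaminant"], "+", "")
    df.to_csv(path, sep="\t")


def load_complex_annotation() -> pd.DataFrame:
    """Bundled protein-complex membership table (protein, complex).

    Lists subunits of the MLL3/MLL4 (COMPASS) H3K4 methyltransferase, PR-DUB
    H2A deubiquitinase and MiDAC mitotic deacetylase complexes.  Shipped as an
    editable TSV so the biology stays data, not code.
    """
    with resources.files("utxsplice.data").joinpath("complex_subunits.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(matrix: PulldownMatrix, min_replicates: int = 2) -> PulldownMatrix:
    """Row-filter and log2-transform a raw pulldown matrix.

    Removes contaminant and reverse-decoy rows and proteins identified in
    fewer than ``min_replicates`` replicates, then log2-transforms the LFQ
    layer (missing stays missing).  The three row filters commute, so their
    order is immaterial.
    """
    for g, reps in matrix.groups.items():
        if len(reps) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    f = matrix.flags
    keep = (
        ~f["is_contaminant"].astype(bool)
        & ~f["is_reverse"].astype(bool)
        & (f["n_replicates_identified"] >= min_replicates)
    )
    idx = matrix.proteins[keep.reindex(matrix.proteins).fillna(False).astype(bool)]
    lfq = matrix.lfq.loc[idx]
    if not matrix.log2_scale:
        lfq = np.log2(lfq.mask(lfq <= 0))
    return replace(matrix, lfq=lfq, ibaq=matrix.ibaq.loc[idx], flags=f.loc[idx], log2_scale=True)


def impute(
    matrix: PulldownMatrix,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int | np.random.Generator = 0,
) -> PulldownMatrix:
    """Impute missing log2 intensities from a down-shifted Gaussian.

    Per replicate column with observed mean m and standard deviation s,
    missing cells are drawn from Normal(m - shift*s, (width*s)^2): the
    conventional left-censoring model in which unobserved proteins sit below
    the detection limit.  Deterministic for a fixed seed.
    """
    if not matrix.log2_scale:
        raise ValueError("impute expects a log2-transformed matrix; run preprocess first")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lfq = matrix.lfq.copy()
    for col in lfq.columns:
        vals = lfq[col]
        observed = vals.dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} fully missing; cannot impute")
        n_missing = int(vals.isna().sum())
        if n_missing == 0:
            continue
        m, s = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(m - shift * s, width * s, size=n_missing)
        lfq.loc[vals.isna(), col] = draws
    return replace(matrix, lfq=lfq)


# ---------------------------------------------------------------------------
# S0 t-test with permutation FDR


def _s0_statistics(a: np.ndarray, b: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise difference of means and S0-moderated t statistic (a vs b)."""
    n1, n2 = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = diff / (s0 + se)
    stat = np.where((se == 0) & (diff == 0), 0.0, stat)
    return diff, stat


def _label_permutations(
    n1: int, n2: int, n_permutations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distinct group-label permutations, excluding the identity and its complement.

    Those two reassignments reproduce the observed |statistic| exactly, so a
    strong true positive would otherwise inflate its own null distribution.
    """
    n = n1 + n2
    identity = frozenset(range(n1))
    complement = frozenset(range(n1, n))
    all_splits = [frozenset(c) for c in itertools.combinations(range(n), n1)]
    usable = [s for s in all_splits if s not in (identity, complement)]
    if len(usable) > n_permutations:
        chosen = rng.choice(len(usable), size=n_permutations, replace=False)
        usable = [usable[i] for i in chosen]
    return [np.array(sorted(s)) for s in usable]


def s0_ttest(
    matrix: PulldownMatrix,
    s0: float = 1.0,
    fdr: float = 0.01,
    n_permutations: int = 250,
    seed: int | np.random.Generator = 0,
    group_a: str = "GFP",
    group_b: str = "control",
    min_permutations: int = 10,
) -> pd.DataFrame:
    """Two-sided S0-moderated t-test of ``group_a`` vs ``group_b`` enrichment.

    Returns a per-protein frame with columns ``difference`` (log2 mean
    difference), ``statistic``, ``p_value`` (classical Student t, two-sided),
    ``q_value`` (estimated FDR at each protein's |statistic| threshold) and
    ``significant``.  Significance is controlled at ``fdr`` by the
    permutation-threshold procedure; when fewer than ``min_permutations``
    distinct label permutations exist the test falls back to
    Benjamini-Hochberg on the parametric p-values.
    """
    if not matrix.log2_scale:
        raise ValueError("s0_ttest expects a log2-transformed (and imputed) matrix")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols_a = matrix.group_columns(group_a)
    cols_b = matrix.group_columns(group_b)
    a = matrix.lfq[cols_a].to_numpy(float)
    b = matrix.lfq[cols_b].to_numpy(float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("matrix still has missing values; impute first")
    n1, n2 = a.shape[1], b.shape[1]
    diff, stat = _s0_statistics(a, b, s0)

    # classical parametric p (s0 = 0 statistic, Student t with pooled variance)
    _, t_classic = _s0_statistics(a, b, s0=0.0)
    dof = n1 + n2 - 2
    p_classic = 2.0 * stats.t.sf(np.abs(t_classic), df=dof)

    perms = _label_permutations(n1, n2, n_permutations, rng)
    data = np.hstack([a, b])
    abs_stat = np.abs(stat)

    if len(perms) < min_permutations:
        from statsmodels.stats.multitest import multipletests

        significant, q, _, _ = multipletests(p_classic, alpha=fdr, method="fdr_bh")
        method = "bh"
    else:
        perm_abs = np.empty((len(perms), len(abs_stat)))
        idx_all = np.arange(n1 + n2)
        for k, ia in enumerate(perms):
            ib = np.setdiff1d(idx_all, ia, assume_unique=True)
            _, ps = _s0_statistics(data[:, ia], data[:, ib], s0)
            perm_abs[k] = np.abs(ps)
        perm_sorted = np.sort(perm_abs.ravel())
        obs_sorted = np.sort(abs_stat)
        n_perm = len(perms)
        # estimated FDR at threshold t: mean perm count >= t over observed count >= t
        n_perm_ge = len(perm_sorted) - np.searchsorted(perm_sorted, abs_stat, side="left")
        n_obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, abs_stat, side="left")
        # add-one smoothing (Phipson & Smyth): with finitely many permutations
        # the expected null count — and hence the FDR — is never estimated as 0
        q = ((n_perm_ge + 1.0) / (n_perm + 1.0)) / np.maximum(n_obs_ge, 1)
        q = np.minimum(q, 1.0)
        # each protein's q is the best (lowest) estimated FDR over all
        # thresholds that still include it, i.e. thresholds <= its |statistic|:
        # running minimum in ascending |statistic| order
        order = np.argsort(abs_stat)
        q_ord = np.minimum.accumulate(q[order])
        q = np.empty_like(q_ord)
        q[order] = q_ord
        significant = q <= fdr
        method = "permutation"

    return pd.DataFrame(
        {
            "difference": diff,
            "statistic": stat,
            "p_value": p_classic,
            "q_value": q,
            "significant": significant,
            "method": method,
        },
        index=matrix.proteins,
    )


# ---------------------------------------------------------------------------
# iBAQ stoichiometry


def stoichiometry(
    matrix: PulldownMatrix,
    anchor: str = "PAXIP1",
    complexes: pd.DataFrame | None = None,
    group_a: str = "GFP",
    group_b: str = "control",
) -> pd.DataFrame:
    """Control-subtracted iBAQ abundance relative to an anchor subunit.

    Per protein, each GFP-replicate iBAQ value has the mean control iBAQ
    subtracted; the replicate mean is clipped at zero (negative abundances
    are subtraction artifacts) and divided by the anchor protein's value.
    Returns columns ``mean_ibaq`` (control-subtracted), ``ratio``, ``sd``
    (of per-replicate ratios, for error bars) and ``complex``.
    """
    cols_a = matrix.group_columns(group_a)
    cols_b = matrix.group_columns(group_b)
    gfp = matrix.ibaq[cols_a].fillna(0.0)
    ctrl_mean = matrix.ibaq[cols_b].fillna(0.0).mean(axis=1)
    sub = gfp.sub(ctrl_mean, axis=0)
    mean_sub = sub.mean(axis=1).clip(lower=0.0)
    if anchor not in matrix.proteins:
        raise ValueError(f"anchor {anchor!r} missing from matrix")
    anchor_val = mean_sub.loc[anchor]
    if not anchor_val > 0:
        raise ValueError(f"anchor {anchor!r} has non-positive control-subtracted iBAQ")
    ratio = mean_sub / anchor_val
    per_rep_ratio = sub / anchor_val
    out = pd.DataFrame(
        {
            "mean_ibaq": mean_sub,
            "ratio": ratio,
            "sd": per_rep_ratio.std(axis=1, ddof=1),
        },
        index=matrix.proteins,
    )
    if complexes is None:
        try:
            complexes = load_complex_annotation()
        except FileNotFoundError:  # pragma: no cover
            complexes = pd.DataFrame(columns=["protein", "complex"])
    label = complexes.set_index("protein")["complex"] if len(complexes) else pd.Series(dtype=str)
    out["complex"] = [label.get(p, "other") for p in out.index]
    return out
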
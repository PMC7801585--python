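"""Expression classification and enrichment statistics.

Genes are called *expressed* in a sample when their TPM strictly exceeds
that sample's N99 value, and *highly expressed* when a one-sided Z-test on
log2(TPM+1) among the sample's expressed genes gives p < α (α = 0.01 for
developmental stages, 0.05 for the venom gland). The N99 value is read
assembly-style by default: sort TPM descending and take the value at which
the cumulative sum first reaches 99% of the total (a plain 99th-percentile
reading is selectable).

Venom specialization of a gene is its venom-gland share of row-total TPM,
in [0, 1]. Enrichment of gene sets among highly expressed genes uses the
exact hypergeometric tail with Bonferroni and Benjamini–Hochberg control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import ExpressionMatrix

__all__ = [
    "ExpressionCalls",
    "SpecializationProfile",
    "EnrichmentResult",
    "n99_threshold",
    "classify_expressed",
    "classify_high",
    "specialization_index",
    "exclusive_concurrence",
    "hypergeom_tail",
    "bonferroni",
    "bh_fdr",
    "specific_gene_enrichment",
]


@dataclass
class ExpressionCalls:
    """Per-sample expressed / highly-expressed gene sets with thresholds."""

    thresholds: dict[str, float]            # sample -> N99 TPM
    expressed: dict[str, set[str]]          # sample -> gene set
    high: dict[str, set[str]] = field(default_factory=dict)
    alpha: dict[str, float] = field(default_factory=dict)

    def expressed_anywhere(self) -> set[str]:
        out: set[str] = set()
        for s in self.expressed.values():
            out |= s
        return out


def n99_threshold(tpm: Sequence[float], mode: str = "cumulative") -> float:
    """The N99 expression cutoff of one sample.

    ``cumulative`` (default): sort descending; the threshold is the TPM of
    the first gene at which the running sum reaches ≥ 99% of the total —
    the N50-family reading. ``percentile``: the 99th percentile of the
    TPM vector.
    """
    arr = np.asarray(tpm, dtype=float)
    if arr.size == 0:
        raise ValueError("empty TPM vector")
    if (arr < 0).any():
        raise ValueError("negative TPM")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero TPM vector has no N99 value")
    if mode == "percentile":
        return float(np.percentile(arr, 99))
    if mode != "cumulative":
        raise ValueError(f"unknown N99 mode {mode!r}")
    desc = np.sort(arr)[::-1]
    cum = np.cumsum(desc)
    idx = int(np.searchsorted(cum, 0.99 * total))
    return float(desc[min(idx, desc.size - 1)])


def classify_expressed(matrix: ExpressionMatrix,
                       mode: str = "cumulative") -> ExpressionCalls:
    """Call expressed genes per sample: TPM strictly above the sample N99."""
    thresholds: dict[str, float] = {}
    expressed: dict[str, set[str]] = {}
    for sample in matrix.sample_ids:
        col = matrix.values[sample]
        thr = n99_threshold(col.to_numpy(), mode=mode)
        thresholds[sample] = thr
        expressed[sample] = set(col.index[col > thr])
    return ExpressionCalls(thresholds=thresholds, expressed=expressed)


def classify_high(matrix: ExpressionMatrix,
                  calls: ExpressionCalls | None = None,
                  alpha_stage: float = 0.01,
                  alpha_vg: float = 0.05,
                  mode: str = "cumulative") -> ExpressionCalls:
    """Call highly expressed genes per sample.

    Among each sample's expressed genes, log2(TPM+1) is z-scored and a gene
    is highly expressed when the one-sided upper-tail normal p-value falls
    below α. Zero variance among expressed genes yields no calls (with a
    warning).
    """
    if calls is None:
        calls = classify_expressed(matrix, mode=mode)
    vg = set(matrix.venom_gland_samples())
    high: dict[str, set[str]] = {}
    alpha_used: dict[str, float] = {}
    for sample in matrix.sample_ids:
        alpha = alpha_vg if sample in vg else alpha_stage
        alpha_used[sample] = alpha
        expr = sorted(calls.expressed[sample])
        if len(expr) < 3:
            raise ValueError(
                f"sample {sample!r}: fewer than 3 expressed genes")
        logv = np.log2(matrix.values.loc[expr, sample].to_numpy() + 1.0)
        sd = logv.std(ddof=1)
        if sd == 0.0:
            warnings.warn(f"sample {sample!r}: zero variance among expressed "
                          "genes; no high-expression calls")
            high[sample] = set()
            continue
        z = (logv - logv.mean()) / sd
        p = stats.norm.sf(z)
        high[sample] = {g for g, pp in zip(expr, p) if pp < alpha}
    return ExpressionCalls(thresholds=calls.thresholds,
                           expressed=calls.expressed,
                           high=high, alpha=alpha_used)


@dataclass
class SpecializationProfile:
    """Per-gene specialization toward a target sample."""

    target_sample: str
    index: dict[str, float]       # gene -> index in [0, 1]
    argmax_sample: dict[str, str]  # gene -> sample of maximal TPM


def specialization_index(matrix: ExpressionMatrix,
                         target_sample: str,
                         mode: str = "share") -> SpecializationProfile:
    """Specialization of each gene toward ``target_sample``.

    ``share`` (default): TPM(gene, target) / Σ_s TPM(gene, s); zero rows
    give 0. ``tau``: the tissue-specificity index
    τ = Σ_s (1 - x_s / x_max) / (n_samples - 1), reported only when the
    target is the gene's argmax sample (else 0).
    """
    if target_sample not in matrix.sample_ids:
        raise KeyError(f"sample {target_sample!r} not in matrix")
    vals = matrix.values
    row_sum = vals.sum(axis=1)
    argmax = vals.idxmax(axis=1)
    index: dict[str, float] = {}
    for g in matrix.gene_ids:
        total = row_sum[g]
        if total == 0:
            index[g] = 0.0
            continue
        if mode == "share":
            index[g] = float(vals.at[g, target_sample] / total)
        elif mode == "tau":
            x = vals.loc[g].to_numpy(dtype=float)
            xmax = x.max()
            tau = float(np.sum(1.0 - x / xmax) / (x.size - 1)) if x.size > 1 else 0.0
            index[g] = tau if argmax[g] == target_sample else 0.0
        else:
            raise ValueError(f"unknown specialization mode {mode!r}")
    return SpecializationProfile(target_sample=target_sample, index=index,
                                 argmax_sample={g: str(argmax[g])
                                                for g in matrix.gene_ids})


def exclusive_concurrence(calls: ExpressionCalls,
                          sample_subset: Iterable[str],
                          stage_universe: Iterable[str]) -> dict[str, bool]:
    """True for genes whose expressed-sample set (within the developmental
    stages) equals exactly ``sample_subset``. The venom gland is excluded
    from the universe by passing only stage samples in ``stage_universe``.
    """
    subset = set(sample_subset)
    universe = list(stage_universe)
    if not subset:
        raise ValueError("empty sample subset")
    if not subset.issubset(universe):
        raise ValueError("subset not contained in the stage universe")
    genes: set[str] = set()
    for s in universe:
        genes |= calls.expressed[s]
    out: dict[str, bool] = {}
    all_genes = set()
    for s in universe:
        all_genes |= calls.expressed.get(s, set())
    for g in sorted(all_genes):
        where = {s for s in universe if g in calls.expressed[s]}
        out[g] = (where == subset)
    return out


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(N: int, K: int, n: int, k: int, tail: str = "upper") -> float:
    """Exact hypergeometric tail probability, evaluated in log space.

    Drawing ``n`` from a population of ``N`` with ``K`` successes:
    upper tail = P(X ≥ k), lower tail = P(X ≤ k).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid bounds N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"invalid k={k} for K={K}, n={n}")
    lo = max(0, n - (N - K))
    hi = min(K, n)
    if tail == "upper":
        support = range(k, hi + 1)
    elif tail == "lower":
        support = range(lo, k + 1)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    denom = _log_comb(N, n)
    logs = [_log_comb(K, x) + _log_comb(N - K, n - x) - denom for x in support]
    if not logs:
        return 0.0
    return float(min(1.0, math.exp(logsumexp(logs))))


def bonferroni(pvals: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: min(1, m·p)."""
    p = np.asarray(pvals, dtype=float)
    _check_unit(p)
    if p.size == 0:
        return []
    return list(np.minimum(1.0, p * p.size))


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    _check_unit(p)
    if p.size == 0:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def _check_unit(p: np.ndarray) -> None:
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of a gene set among per-sample draws."""

    table: pd.DataFrame  # index: sample; N, K, n, k, p, p_bonferroni, q_bh, tail


def specific_gene_enrichment(calls: ExpressionCalls,
                             specific_set: Iterable[str],
                             universe: Iterable[str],
                             tail: str = "upper",
                             samples: Sequence[str] | None = None) -> EnrichmentResult:
    """Enrichment of species-specific genes among each sample's highly
    expressed genes.

    Population = the gene universe; successes = specific genes; draws = the
    sample's highly expressed genes; k = highly expressed specific genes.
    Bonferroni and BH corrections run across samples.
    """
    uni = set(universe)
    spec = set(specific_set) & uni
    if samples is None:
        samples = sorted(calls.high)
    rows = []
    for s in samples:
        drawn = calls.high.get(s, set()) & uni
        k = len(drawn & spec)
        p = hypergeom_tail(len(uni), len(spec), len(drawn), k, tail=tail)
        rows.append((s, len(uni), len(spec), len(drawn), k, p))
    pvals = [r[5] for r in rows]
    table = pd.DataFrame(
        {"N": [r[1] for r in rows], "K": [r[2] for r in rows],
         "n": [r[3] for r in rows], "k": [r[4] for r in rows],
         "p": pvals,
         "p_bonferroni": bonferroni(pvals),
         "q_bh": bh_fdr(pvals),
         "tail": tail},
        index=pd.Index([r[0] for r in rows], name="sample"),
    )
    return EnrichmentResult(table=table)
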
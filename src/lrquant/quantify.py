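"""Abundance estimation: effective lengths, EM, and the abundance table.

Effective length is transcript-specific and estimated from the data: for
transcript t,

    l_e(t) = ( sum of read lengths over reads whose TCC contains t )
             / ( number of such reads )  -  k

computed over the first ``cap`` (default 1,000,000) mapped reads.  For
long reads the read length distribution — not a fragment-length model —
carries the length bias, and a read informs every transcript in its class.
Transcripts untouched by those reads fall back to annotated length - k;
all values are clamped to >= 1.  With ``length_norm=False`` every l_e is 1
and quantification reduces to pure count apportionment (the recommended
default for high/non-uniform error rates).

Two EM flavors apportion multi-mapping reads:

* ``default`` — standard EM over all classes, initialized at unique counts
  plus uniform shares of the multi-mapping counts;
* ``longread`` — EM over multi-transcript classes only, initialized
  uniformly on their members; after convergence the uniquely-mapping
  counts are added to each transcript.

Both conserve the total number of mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pseudoalign import TCCCounts, pseudoalign_batch
from .tdbg import TDBGIndex

__all__ = [
    "EffectiveLengths",
    "EMResult",
    "QuantResult",
    "estimate_effective_lengths",
    "run_em",
    "compute_tpm",
    "make_abundance_table",
    "write_abundance",
    "read_abundance",
    "quantify",
]

DEFAULT_EFF_LEN_CAP = 1_000_000
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITERS = 10_000


@dataclass
class EffectiveLengths:
    l_e: np.ndarray  # per-transcript effective length, > 0
    n_reads_used: int
    fallback_used: np.ndarray  # bool per transcript


@dataclass
class EMResult:
    est_counts: np.ndarray
    n_iters: int
    log_likelihoods: list
    converged: bool


@dataclass
class QuantResult:
    table: pd.DataFrame
    tcc_counts: TCCCounts
    classifications: list
    mapping_rate: float
    eff_lengths: EffectiveLengths
    em: EMResult


def estimate_effective_lengths(
    classifications,
    index: TDBGIndex,
    cap: int = DEFAULT_EFF_LEN_CAP,
    length_norm: bool = True,
) -> EffectiveLengths:
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    T = index.n_transcripts
    if not length_norm:
        return EffectiveLengths(np.ones(T), 0, np.zeros(T, dtype=bool))
    length_sum = np.zeros(T)
    n_reads = np.zeros(T)
    used = 0
    for rc in classifications:
        if rc.tcc is None:
            continue
        if used >= cap:
            break
        used += 1
        for t in rc.tcc:
            length_sum[t] += rc.read_length
            n_reads[t] += 1
    fallback = n_reads == 0
    l_e = np.empty(T)
    with np.errstate(invalid="ignore", divide="ignore"):
        l_e[~fallback] = length_sum[~fallback] / n_reads[~fallback] - index.k
    l_e[fallback] = np.asarray(index.transcript_lengths, dtype=float)[fallback] - index.k
    return EffectiveLengths(np.maximum(l_e, 1.0), used, fallback)


def _flatten(classes):
    """Flatten [(tcc, count), ...] into member/class/count arrays."""
    mem = np.array([t for tcc, _ in classes for t in tcc], dtype=np.intp)
    cls = np.array(
        [ci for ci, (tcc, _) in enumerate(classes) for _ in tcc], dtype=np.intp
    )
    n_c = np.array([n for _, n in classes], dtype=float)
    return mem, cls, n_c


def run_em(
    tcc_counts: TCCCounts,
    eff_lengths: EffectiveLengths,
    mode: str = "longread",
    tol: float = DEFAULT_TOL,
    max_iters: int = DEFAULT_MAX_ITERS,
) -> EMResult:
    """EM apportionment of class counts into per-transcript counts.

    The update is  alpha_t <- sum_c n_c * (alpha_t/l_t) / sum_{u in c} alpha_u/l_u
    over the active classes; the observed-data log-likelihood
    sum_c n_c log( sum_{t in c} alpha_t/l_t )  (total alpha is constant) is
    recorded every iteration and is non-decreasing.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    if mode not in ("default", "longread"):
        raise ValueError(f"unknown EM mode {mode!r}")
    l_e = np.asarray(eff_lengths.l_e, dtype=float)
    T = l_e.size

    items = sorted(tcc_counts.counts.items())
    unique = np.zeros(T)
    for tcc, n in items:
        if len(tcc) == 1:
            unique[tcc[0]] += n
    multi = [(tcc, n) for tcc, n in items if len(tcc) >= 2]

    if mode == "default":
        active = items
        alpha = unique.copy()
    else:
        active = multi
        alpha = np.zeros(T)
    for tcc, n in multi:
        alpha[list(tcc)] += n / len(tcc)

    log_liks: list = []
    n_iters = 0
    converged = True
    if active:
        mem, cls, n_c = _flatten(active)
        C = len(active)
        converged = False
        for n_iters in range(1, max_iters + 1):
            w = alpha / l_e
            cw = np.zeros(C)
            np.add.at(cw, cls, w[mem])
            with np.errstate(divide="ignore"):
                log_liks.append(float(n_c @ np.log(cw)))
            safe = np.where(cw == 0.0, 1.0, cw)
            contrib = n_c[cls] * w[mem] / safe[cls]
            alpha_new = np.zeros(T)
            np.add.at(alpha_new, mem, contrib)
            delta = np.abs(alpha_new - alpha) / np.maximum(alpha_new, 1e-10)
            alpha = alpha_new
            if delta.max() < tol:
                converged = True
                break

    if mode == "longread":
        alpha = alpha + unique
    return EMResult(alpha, n_iters, log_liks, converged)


def compute_tpm(est_counts, eff_lengths) -> np.ndarray:
    """TPM: per-transcript read density normalized to sum to 1e6."""
    est = np.asarray(est_counts, dtype=float)
    l_e = eff_lengths.l_e if isinstance(eff_lengths, EffectiveLengths) else eff_lengths
    dens = est / np.asarray(l_e, dtype=float)
    total = dens.sum()
    if total <= 0:
        return np.zeros_like(dens)
    return 1e6 * dens / total


def make_abundance_table(
    transcript_ids, transcript_lengths, eff_lengths, est_counts
) -> pd.DataFrame:
    l_e = eff_lengths.l_e if isinstance(eff_lengths, EffectiveLengths) else eff_lengths
    tpm = compute_tpm(est_counts, l_e) if len(np.atleast_1d(l_e)) else np.array([])
    return pd.DataFrame(
        {
            "target_id": list(transcript_ids),
            "length": list(transcript_lengths),
            "eff_length": np.asarray(l_e, dtype=float),
            "est_counts": np.asarray(est_counts, dtype=float),
            "tpm": tpm,
        }
    )


def write_abundance(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_abundance(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def quantify(
    index: TDBGIndex,
    reads,
    em_mode: str = "longread",
    length_norm: bool = False,
    eff_len_cap: int = DEFAULT_EFF_LEN_CAP,
    tol: float = DEFAULT_TOL,
    max_iters: int = DEFAULT_MAX_ITERS,
) -> QuantResult:
    """Full pipeline: pseudoalign, estimate effective lengths, EM, table."""
    tcc_counts, classifications, rate = pseudoalign_batch(index, reads)
    eff = estimate_effective_lengths(
        classifications, index, cap=eff_len_cap, length_norm=length_norm
    )
    em = run_em(tcc_counts, eff, mode=em_mode, tol=tol, max_iters=max_iters)
    table = make_abundance_table(
        index.transcript_ids, index.transcript_lengths, eff, em.est_counts
    )
    return QuantResult(table, tcc_counts, classifications, rate, eff, em)
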
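"""Synthetic transcriptomes, expression profiles, and long reads with
profile-parameterized sequencing errors.

The error model is deliberately minimal: per read, the number of error
events is Binomial(read_length, error_rate); each event is independently a
deletion, substitution, or insertion according to the profile's fractions,
placed at a uniformly chosen position.  All indel events are single-base.
Built-in presets follow published platform mixes: ONT — 38.5% deletions,
38.5% substitutions, 23% insertions; PacBio — 24.5% deletions, 52.4%
substitutions, 23.1% insertions.  Reads are full-length by default
(fragment mode emits uniform substrings), with a 50% strand flip so both
orientations are exercised.

Every operation is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tdbg import TranscriptSet, reverse_complement

__all__ = [
    "ErrorProfile",
    "SimTruth",
    "ONT_FRACTIONS",
    "PACBIO_FRACTIONS",
    "generate_transcriptome",
    "sample_expression",
    "generate_reads",
    "inject_errors",
    "write_truth",
]

ONT_FRACTIONS = (0.385, 0.385, 0.23)  # deletions, substitutions, insertions
PACBIO_FRACTIONS = (0.245, 0.524, 0.231)

_BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorProfile:
    error_rate: float
    del_frac: float
    sub_frac: float
    ins_frac: float
    positional_model: str = "uniform"

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")
        fracs = (self.del_frac, self.sub_frac, self.ins_frac)
        if any(f < 0 for f in fracs):
            raise ValueError("error-type fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"error-type fractions must sum to 1, got {sum(fracs)}")
        if self.positional_model != "uniform":
            raise ValueError(f"unknown positional model {self.positional_model!r}")

    @classmethod
    def preset(cls, name: str, error_rate: float) -> "ErrorProfile":
        if name == "ont":
            d, s, i = ONT_FRACTIONS
        elif name == "pacbio":
            d, s, i = PACBIO_FRACTIONS
        else:
            raise ValueError(f"unknown preset {name!r} (expected 'ont' or 'pacbio')")
        return cls(error_rate, d, s, i)


@dataclass
class SimTruth:
    transcript_ids: tuple
    true_counts: np.ndarray  # int, sums to the requested read total
    true_tpm: np.ndarray
    seed: int
    model: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target_id": list(self.transcript_ids),
                "true_counts": self.true_counts.astype(int),
                "true_tpm": self.true_tpm,
            }
        )


def write_truth(truth: SimTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def _random_seq(rng, length: int) -> str:
    return _BASE_ARR[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def generate_transcriptome(
    n_transcripts: int,
    length_range=(500, 2000),
    shared_blocks=None,
    seed: int = 0,
) -> TranscriptSet:
    """Random transcripts; ``shared_blocks`` is a list of
    (source_ordinal, dest_ordinal, block_length) directives, each pasting a
    random window of the source into the destination to plant
    multi-mapping structure."""
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad length_range {length_range}")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_transcripts)
    seqs = [_random_seq(rng, int(L)) for L in lengths]
    for src, dst, block_len in shared_blocks or ():
        if not (0 <= src < n_transcripts and 0 <= dst < n_transcripts):
            raise ValueError(f"shared block ordinals out of range: {(src, dst)}")
        if block_len > len(seqs[src]) or block_len > len(seqs[dst]):
            raise ValueError(
                f"shared block of {block_len} bp does not fit in transcripts "
                f"{src} ({len(seqs[src])} bp) / {dst} ({len(seqs[dst])} bp)"
            )
        s0 = int(rng.integers(0, len(seqs[src]) - block_len + 1))
        block = seqs[src][s0 : s0 + block_len]
        d0 = int(rng.integers(0, len(seqs[dst]) - block_len + 1))
        seqs[dst] = seqs[dst][:d0] + block + seqs[dst][d0 + block_len :]
    return TranscriptSet.from_pairs((f"t{i}", seqs[i]) for i in range(n_transcripts))


def sample_expression(
    transcripts: TranscriptSet,
    n_reads_total: int,
    model: str = "uniform",
    seed: int = 0,
    mu: float = 0.0,
    sigma: float = 1.0,
) -> SimTruth:
    """True per-transcript read counts.

    uniform: as equal as integer division allows, remainder to the lowest
    ordinals.  lognormal: a multinomial draw from normalized lognormal
    weights.  true_tpm is the length-normalized density implied by the
    counts and annotated lengths.
    """
    if n_reads_total < 0:
        raise ValueError("n_reads_total must be >= 0")
    T = len(transcripts)
    rng = np.random.default_rng(seed)
    if model == "uniform":
        base, rem = divmod(n_reads_total, T)
        counts = np.full(T, base, dtype=np.int64)
        counts[:rem] += 1
        desc = "uniform"
    elif model == "lognormal":
        weights = rng.lognormal(mu, sigma, size=T)
        counts = rng.multinomial(n_reads_total, weights / weights.sum())
        desc = f"lognormal(mu={mu},sigma={sigma})"
    else:
        raise ValueError(f"unknown expression model {model!r}")
    dens = counts / np.asarray(transcripts.lengths, dtype=float)
    total = dens.sum()
    tpm = 1e6 * dens / total if total > 0 else np.zeros(T)
    return SimTruth(transcripts.ids, counts, tpm, seed, desc)


def generate_reads(
    transcripts: TranscriptSet,
    truth: SimTruth,
    read_model: str = "full_length",
    min_len: int = 200,
    seed: int = 0,
):
    """Error-free reads per the truth table.

    full_length emits each source transcript's entire sequence; fragment
    emits uniform substrings of length >= min_len (sources shorter than
    min_len are skipped with a warning).  Strand flips with probability
    0.5.  Read ids encode ``<transcript>|r<n>|<strand>`` so the source is
    recoverable.  Returns (reads, n_skipped).
    """
    if read_model not in ("full_length", "fragment"):
        raise ValueError(f"unknown read model {read_model!r}")
    if tuple(truth.transcript_ids) != transcripts.ids:
        raise ValueError("truth table does not match the transcript set")
    rng = np.random.default_rng(seed)
    reads = []
    n_skipped = 0
    for ordinal, (tid, seq) in enumerate(transcripts.records):
        L = len(seq)
        for r in range(int(truth.true_counts[ordinal])):
            if read_model == "full_length":
                s = seq
            else:
                if min_len > L:
                    n_skipped += 1
                    continue
                ln = int(rng.integers(min_len, L + 1))
                st = int(rng.integers(0, L - ln + 1))
                s = seq[st : st + ln]
            strand = "-" if rng.random() < 0.5 else "+"
            if strand == "-":
                s = reverse_complement(s)
            reads.append((f"{tid}|r{r}|{strand}", s))
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} reads from transcripts shorter than "
            f"min_len={min_len}",
            stacklevel=2,
        )
    return reads, n_skipped


def inject_errors(reads, profile: ErrorProfile, seed: int = 0):
    """Mutate reads per the error profile.

    Returns (mutated reads, per-read tallies); each tally is a dict with
    realized ``del``/``sub``/``ins`` event counts.
    """
    rng = np.random.default_rng(seed)
    fracs = np.array([profile.del_frac, profile.sub_frac, profile.ins_frac])
    out = []
    tallies = []
    for rid, seq in reads:
        tally = {"del": 0, "sub": 0, "ins": 0}
        n_events = int(rng.binomial(len(seq), profile.error_rate))
        if n_events:
            s = list(seq)
            for kind in rng.choice(3, size=n_events, p=fracs):
                if kind == 0:  # deletion
                    if not s:
                        continue
                    del s[int(rng.integers(0, len(s)))]
                    tally["del"] += 1
                elif kind == 1:  # substitution
                    if not s:
                        continue
                    pos = int(rng.integers(0, len(s)))
                    cur = s[pos]
                    alts = _BASES.replace(cur, "") if cur in _BASES else _BASES
                    s[pos] = alts[int(rng.integers(0, len(alts)))]
                    tally["sub"] += 1
                else:  # insertion, before a uniform position in [0, len]
                    pos = int(rng.integers(0, len(s) + 1))
                    s.insert(pos, _BASES[int(rng.integers(0, 4))])
                    tally["ins"] += 1
            seq = "".join(s)
        out.append((rid, seq))
        tallies.append(tally)
    return out, tallies
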
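"""3-state (loss/normal/gain) HMM calling on probe-intensity log-ratios.

Pairwise reference orchestration for cohort genotyping arrays: every
sample is compared against every other sample (each animal serving
once as reference), the per-probe intensity difference is decoded with
a Gaussian-emission Viterbi pass, and runs of non-normal states become
calls. Comparing all pairs rather than a single fixed reference avoids
the false negatives a shared-reference design produces for variants
carried by the reference itself.

The emission/transition parameters are package defaults, not derived
quantities: symmetric state means +-0.3 on the log-ratio scale, a
shared emission SD estimated robustly from the track (MAD) unless
given, and a stay probability of 0.999. The HMM is run per chromosome;
no transition crosses a chromosome boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doc_caller import CnvCall

STATES = ("loss", "normal", "gain")
LOSS, NORMAL, GAIN = 0, 1, 2
# argmax preference on exact ties: normal first, then loss, then gain
_TIE_ORDER = (NORMAL, LOSS, GAIN)


@dataclass
class HmmParams:
    """Gaussian-emission HMM parameters for the log-ratio track.

    ``mu`` is the magnitude of the loss/gain state means (loss = -mu,
    normal = 0, gain = +mu); ``sigma`` the shared emission SD (None:
    estimate from the data via 1.4826 * MAD, floored at 0.05); ``rho``
    the self-transition (stay) probability, remaining mass split
    equally between the other two states.
    """

    mu: float = 0.3
    sigma: float | None = None
    rho: float = 0.999

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def means(self) -> np.ndarray:
        return np.array([-self.mu, 0.0, self.mu])

    def log_transition(self) -> np.ndarray:
        switch = (1.0 - self.rho) / 2.0
        T = np.full((3, 3), switch)
        np.fill_diagonal(T, self.rho)
        return np.log(T)

    def resolve_sigma(self, log_ratios: np.ndarray) -> float:
        if self.sigma is not None:
            return self.sigma
        mad = float(np.median(np.abs(log_ratios - np.median(log_ratios))))
        return max(1.4826 * mad, 0.05)


class ProbeIntensity:
    """A probe-by-sample matrix of normalized intensities.

    Wraps a DataFrame with columns ``probe_id``, ``chrom``, ``pos``
    (0-based bp) plus one numeric column per sample; probes are kept
    sorted by (chrom, pos).
    """

    META_COLUMNS = ("probe_id", "chrom", "pos")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.META_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"missing probe columns: {sorted(missing)}")
        self.frame = frame.sort_values(["chrom", "pos"], kind="stable").reset_index(
            drop=True
        )
        self.samples: tuple[str, ...] = tuple(
            c for c in frame.columns if c not in self.META_COLUMNS
        )
        if not self.samples:
            raise ValueError("no sample columns")

    @classmethod
    def from_tsv(cls, path) -> "ProbeIntensity":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def values(self, sample: str) -> np.ndarray:
        return self.frame[sample].to_numpy(dtype=float)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.frame["chrom"] == chrom).to_numpy()


def viterbi_states(log_ratios: np.ndarray, params: HmmParams) -> np.ndarray:
    """Most probable loss/normal/gain path under the Gaussian HMM.

    Uniform initial state distribution; exact ties in the dynamic
    program are broken toward "normal" (then "loss"). Returns an int
    array over {LOSS, NORMAL, GAIN}.
    """
    x = np.asarray(log_ratios, dtype=float)
    if x.size == 0:
        raise ValueError("empty log-ratio track")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite log-ratios")
    sigma = params.resolve_sigma(x)
    means = params.means()
    # Gaussian log-density up to a shared constant
    emit = -0.5 * ((x[:, None] - means[None, :]) / sigma) ** 2
    log_T = params.log_transition()
    n = x.size

    score = np.log(np.full(3, 1.0 / 3.0)) + emit[0]
    back = np.zeros((n, 3), dtype=np.int8)
    for t in range(1, n):
        cand = score[:, None] + log_T  # cand[i, j]: best-so-far into j via i
        best = np.full(3, -np.inf)
        arg = np.zeros(3, dtype=np.int8)
        for i in _TIE_ORDER:
            better = cand[i] > best
            best = np.where(better, cand[i], best)
            arg = np.where(better, i, arg)
        score = best + emit[t]
        back[t] = arg

    last = _TIE_ORDER[int(np.argmax([score[s] for s in _TIE_ORDER]))]
    path = np.empty(n, dtype=np.int8)
    path[-1] = last
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def states_to_calls(
    states: np.ndarray, positions: np.ndarray, chrom: str
) -> list[CnvCall]:
    """Turn maximal non-normal state runs into calls.

    A call spans from the first probe position of the run to the last
    probe position + 1 (half-open). Fold change and q statistics do not
    apply to intensity calls and are reported as 0.
    """
    states = np.asarray(states)
    positions = np.asarray(positions)
    if states.shape != positions.shape:
        raise ValueError("states and positions not aligned")
    calls: list[CnvCall] = []
    i, n = 0, len(states)
    while i < n:
        s = states[i]
        j = i
        while j < n and states[j] == s:
            j += 1
        if s != NORMAL:
            calls.append(
                CnvCall(
                    chrom=chrom,
                    start=int(positions[i]),
                    end=int(positions[j - 1]) + 1,
                    n_bins=j - i,
                    direction="gain" if s == GAIN else "loss",
                    log2_fold_change=0.0,
                    min_neglog_q=0.0,
                    mean_neglog_q=0.0,
                )
            )
        i = j
    return calls


@dataclass
class PairwiseCallSet:
    """Calls from one test-vs-reference comparison (direction: test side)."""

    test: str
    reference: str
    calls: list[CnvCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.test == self.reference:
            raise ValueError("test and reference must differ")


def call_pair(
    intensities: ProbeIntensity, test: str, reference: str, params: HmmParams
) -> PairwiseCallSet:
    """HMM-call one sample pair, chromosome by chromosome."""
    ratio = intensities.values(test) - intensities.values(reference)
    calls: list[CnvCall] = []
    for chrom in intensities.chromosomes():
        mask = intensities.chrom_mask(chrom)
        states = viterbi_states(ratio[mask], params)
        pos = intensities.frame.loc[mask, "pos"].to_numpy()
        calls.extend(states_to_calls(states, pos, chrom))
    return PairwiseCallSet(test=test, reference=reference, calls=calls)


def pairwise_calls(
    intensities: ProbeIntensity,
    params: HmmParams | None = None,
    ordered: bool = False,
) -> list[PairwiseCallSet]:
    """All-pairs HMM calling: n samples -> n(n-1)/2 comparisons.

    Each unordered pair is decoded once (a comparison and its reverse
    carry the same intervals with gain/loss swapped); ``ordered=True``
    runs both directions explicitly.
    """
    samples = intensities.samples
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if params is None:
        params = HmmParams()
    pair_iter = (
        itertools.permutations(samples, 2)
        if ordered
        else itertools.combinations(samples, 2)
    )
    return [call_pair(intensities, t, r, params) for t, r in pair_iter]
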
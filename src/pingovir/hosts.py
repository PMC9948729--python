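"""Host linking: CRISPR spacers, k-mer host models, and the
co-abundance interaction network.

Three independent lines of evidence connect a phage to a candidate
bacterial host:

* ``crispr`` — a spacer stored in the host's CRISPR array matches the
  phage (protospacer) at >90% identity over >=80% of the spacer;
* ``markov`` — the phage's composition is unusually likely under a
  k-mer Markov model trained on the host genome, relative to a null of
  decoy phage genomes;
* ``correlation`` — the phage's and host's normalized abundances are
  strongly anticorrelated across producers (Spearman rho <= -0.8 at
  p <= 0.05), the signature expected of predation.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .config import PipelineConfig
from .io import ContigRecord, SampleMetadata
from .triage import revcomp

__all__ = [
    "CrisprArray",
    "SpacerHit",
    "MarkovHostModel",
    "InteractionEdge",
    "detect_crispr_arrays",
    "match_spacers",
    "train_markov_model",
    "predict_host",
    "spearman_assoc",
    "build_network",
]

REPEAT_LEN_RANGE = (21, 48)
SPACER_LEN_RANGE = (20, 55)
SEED_K = 16


@dataclass
class CrisprArray:
    host_id: str
    start: int
    end: int
    repeat_consensus: str
    n_repeats: int
    spacers: list[tuple[int, str]]  # (offset in host genome, sequence)


@dataclass(frozen=True)
class SpacerHit:
    host_id: str
    spacer_index: int
    votu_id: str
    identity: float  # percent over aligned columns
    qcov: float      # aligned fraction of the spacer
    offset: int      # start of the aligned region in the target
    strand: str


@dataclass
class MarkovHostModel:
    host_id: str
    order: int
    log_probs: np.ndarray  # (4^k, 4) log transition probabilities
    null_mu: float
    null_sigma: float


@dataclass
class InteractionEdge:
    phage_id: str
    host_id: str
    rho: float
    p_value: float
    evidence: list[str]  # subset of {correlation, crispr, markov}


# ---------------------------------------------------------------------------
# CRISPR detection

def detect_crispr_arrays(
    genome: ContigRecord,
    min_repeats: int = 3,
    seed_k: int = SEED_K,
    repeat_identity_min: float = 100.0,
) -> list[CrisprArray]:
    """Seeded tandem-repeat scan for CRISPR arrays.

    Looks for >=3 exact occurrences of a seed k-mer whose successive
    start-to-start gaps are consistent with repeat+spacer geometry
    (repeat 21-48 nt, spacer 20-55 nt), extends seeds to the maximal
    repeat (identical copies at the default ``repeat_identity_min`` of
    100; a modal-consensus extension below that), and reports
    non-overlapping arrays leftmost first.  Spacers must be mutually
    non-identical — a tandem repeat with identical "spacers" is a
    satellite, not a CRISPR array.
    """
    seq = genome.seq
    n = len(seq)
    if n < 200:
        raise ValueError(f"genome {genome.id} shorter than 200 nt")
    gap_lo = REPEAT_LEN_RANGE[0] + SPACER_LEN_RANGE[0]
    gap_hi = REPEAT_LEN_RANGE[1] + SPACER_LEN_RANGE[1]
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - seed_k + 1):
        kmer = seq[i : i + seed_k]
        if "N" not in kmer:
            index[kmer].append(i)
    candidates = [ps for ps in index.values() if len(ps) >= min_repeats]
    # enumerate every candidate array first, then resolve overlaps:
    # among overlapping candidates the one with more repeats wins (a
    # sub-run of a longer array must never shadow it), ties leftmost.
    proposals: dict[tuple[int, int, str], CrisprArray] = {}
    for positions in candidates:
        # maximal runs of occurrences with plausible periodicity
        runs: list[list[int]] = []
        run = [positions[0]]
        for p in positions[1:]:
            if gap_lo <= p - run[-1] <= gap_hi:
                run.append(p)
            else:
                runs.append(run)
                run = [p]
        runs.append(run)
        for run in runs:
            if len(run) < min_repeats:
                continue
            array = _extend_run(seq, run, seed_k, repeat_identity_min)
            if array is None:
                continue
            start, end, repeat, starts = array
            rep_len = len(repeat)
            spacers = [
                (starts[i] + rep_len, seq[starts[i] + rep_len : starts[i + 1]])
                for i in range(len(starts) - 1)
            ]
            if not all(
                SPACER_LEN_RANGE[0] <= len(s) <= SPACER_LEN_RANGE[1] for _, s in spacers
            ):
                continue
            if len({s for _, s in spacers}) != len(spacers):
                continue
            proposals[(start, end, repeat)] = CrisprArray(
                genome.id, start, end, repeat, len(starts), spacers
            )
    arrays: list[CrisprArray] = []
    claimed: list[tuple[int, int]] = []
    for cand in sorted(proposals.values(), key=lambda a: (-a.n_repeats, a.start, a.end)):
        if any(cand.start < hi and lo < cand.end for lo, hi in claimed):
            continue
        arrays.append(cand)
        claimed.append((cand.start, cand.end))
    arrays.sort(key=lambda a: a.start)
    return arrays


def _extend_run(
    seq: str, run: list[int], seed_k: int, repeat_identity_min: float
) -> tuple[int, int, str, list[int]] | None:
    """Extend seed occurrences to the maximal repeat; returns
    (array_start, array_end, repeat, repeat_starts) or None."""
    frac = repeat_identity_min / 100.0
    max_extra = REPEAT_LEN_RANGE[1] - seed_k  # never extend beyond a legal repeat

    def column_ok(offsets: int, left: bool) -> tuple[bool, str]:
        bases = []
        for p in run:
            pos = p - offsets if left else p + seed_k + offsets - 1
            if pos < 0 or pos >= len(seq):
                return False, ""
            bases.append(seq[pos])
        modal = max(set(bases), key=bases.count)
        if modal == "N":
            return False, ""
        return bases.count(modal) / len(bases) >= frac, modal

    left = 0
    left_bases: list[str] = []
    while left < max_extra:
        ok, modal = column_ok(left + 1, True)
        if not ok:
            break
        left += 1
        left_bases.append(modal)
    right = 0
    right_bases: list[str] = []
    while left + right < max_extra:
        ok, modal = column_ok(right + 1, False)
        if not ok:
            break
        right += 1
        right_bases.append(modal)
    rep_len = left + seed_k + right
    if not REPEAT_LEN_RANGE[0] <= rep_len <= REPEAT_LEN_RANGE[1]:
        return None
    starts = [p - left for p in run]
    # successive repeats must not overlap (spacer length >= minimum re-checked later)
    for a, b in zip(starts, starts[1:]):
        if b - a < rep_len:
            return None
    repeat = "".join(reversed(left_bases)) + seq[run[0] : run[0] + seed_k] + "".join(right_bases)
    return starts[0], starts[-1] + rep_len, repeat, starts


# ---------------------------------------------------------------------------
# spacer matching

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _match_counts(target: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Matches of ``query`` at every full-overlap offset of ``target``
    (ungapped); N never matches."""
    L = len(query)
    windows = np.lib.stride_tricks.sliding_window_view(target, L)
    eq = (windows == query) & (query != ord("N")) & (windows != ord("N"))
    return eq.sum(axis=1)


def match_spacers(
    spacers: list[tuple[str, int, str]],
    targets: list[ContigRecord],
    identity_min: float = 90.0,
    qcov_min: float = 0.80,
) -> list[SpacerHit]:
    """Ungapped spacer-to-catalog matching on both strands.

    ``spacers`` is a list of (host_id, spacer_index, sequence).  The
    best alignment per (spacer, target) is reported iff its identity
    (matches / aligned columns) strictly exceeds ``identity_min`` and
    it spans at least ``qcov_min`` of the spacer.  Overhanging
    alignments at target ends are scored over the overlapping columns
    only.
    """
    hits: list[SpacerHit] = []
    encoded_targets = [(t, _encode(t.seq)) for t in targets]
    for host_id, spacer_index, spacer in spacers:
        L = len(spacer)
        min_cols = max(1, math.ceil(qcov_min * L))
        variants = [("+", spacer), ("-", revcomp(spacer))]
        for target, tarr in encoded_targets:
            best: tuple[float, float, int, str] | None = None  # identity, qcov, offset, strand
            for strand, s in variants:
                sarr = _encode(s)
                if len(tarr) >= L:
                    counts = _match_counts(tarr, sarr)
                    if counts.size:
                        off = int(counts.argmax())
                        cand = (100.0 * counts[off] / L, 1.0, off, strand)
                        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                            best = cand
                # overhanging alignments at the target ends
                for cols in range(min_cols, L):
                    if cols > len(tarr):
                        continue
                    # spacer tail aligned to target head
                    m = int(((sarr[L - cols :] == tarr[:cols]) & (sarr[L - cols :] != ord("N"))).sum())
                    cand = (100.0 * m / cols, cols / L, 0, strand)
                    if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                        best = cand
                    # spacer head aligned to target tail
                    m = int(((sarr[:cols] == tarr[len(tarr) - cols :]) & (sarr[:cols] != ord("N"))).sum())
                    cand = (100.0 * m / cols, cols / L, len(tarr) - cols, strand)
                    if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                        best = cand
            if best is not None and best[0] > identity_min and best[1] >= qcov_min:
                hits.append(
                    SpacerHit(
                        host_id=host_id,
                        spacer_index=spacer_index,
                        votu_id=target.id,
                        identity=best[0],
                        qcov=best[1],
                        offset=best[2],
                        strand=best[3],
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# Markov host models

def _kmer_contexts(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(context index, next base index) pairs over one strand,
    skipping windows containing N."""
    codes = np.array([_ENC[c] for c in seq], dtype=np.int64)
    n = len(codes)
    if n <= k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    valid = codes < 4
    powers = 4 ** np.arange(k - 1, -1, -1)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)[:-1]
    window_valid = np.lib.stride_tricks.sliding_window_view(valid, k)[:-1].all(axis=1)
    nxt = codes[k:]
    ok = window_valid & (nxt < 4)
    contexts = (windows[ok] * powers).sum(axis=1)
    return contexts, nxt[ok]


def train_markov_model(
    genome: ContigRecord,
    order: int,
    decoy_phages: list[ContigRecord],
) -> MarkovHostModel:
    """Order-k Markov model of a host genome with a decoy null.

    Transition counts are accumulated over both strands with add-one
    smoothing.  The null distribution (mu, sigma) is the mean and
    standard deviation of the per-nucleotide log-likelihood of each
    decoy phage under this model.
    """
    if not 1 <= order <= 8:
        raise ValueError("order must be in [1, 8]")
    if not decoy_phages:
        raise ValueError("decoy set must be nonempty")
    counts = np.ones((4**order, 4), dtype=float)  # add-one pseudocounts
    for strand_seq in (genome.seq, revcomp(genome.seq)):
        ctx, nxt = _kmer_contexts(strand_seq, order)
        np.add.at(counts, (ctx, nxt), 1.0)
    log_probs = np.log(counts / counts.sum(axis=1, keepdims=True))
    model = MarkovHostModel(genome.id, order, log_probs, 0.0, 1.0)
    scores = np.array([score_sequence(model, d.seq) for d in decoy_phages])
    model.null_mu = float(scores.mean())
    sigma = float(scores.std(ddof=1)) if len(scores) > 1 else 0.0
    model.null_sigma = sigma if sigma > 0 else 1e-9
    return model


def score_sequence(model: MarkovHostModel, seq: str) -> float:
    """Per-nucleotide log-likelihood of a sequence under the model."""
    ctx, nxt = _kmer_contexts(seq, model.order)
    if len(ctx) == 0:
        raise ValueError("sequence too short to score")
    return float(model.log_probs[ctx, nxt].mean())


def predict_host(
    phage: ContigRecord, models: list[MarkovHostModel]
) -> list[tuple[str, float, float]]:
    """Rank candidate hosts for a phage.

    Returns (host_id, per-nt log-likelihood, upper-tail Gaussian
    p-value under that host's decoy null), best host first; ties break
    by host_id.
    """
    if not models:
        raise ValueError("empty model list")
    if len(phage.seq) < 500:
        raise ValueError(f"phage {phage.id} shorter than 500 nt")
    rows = []
    for m in models:
        ll = score_sequence(m, phage.seq)
        p = float(norm.sf((ll - m.null_mu) / m.null_sigma))
        rows.append((m.host_id, ll, p))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


# ---------------------------------------------------------------------------
# Spearman association and the network

@lru_cache(maxsize=512)
def _exact_abs_rho_distribution(xr: tuple, yr: tuple) -> np.ndarray:
    """Sorted |rho| over all permutations of the y ranks against the x
    ranks (average-rank ties respected).  The distribution depends only
    on the two rank multisets, so callers pass sorted tuples to share
    cache entries across pairs."""
    x = np.array(xr, dtype=float)
    x = (x - x.mean()) / np.sqrt(((x - x.mean()) ** 2).sum())
    vals = []
    y = np.array(yr, dtype=float)
    ym = y.mean()
    ss = np.sqrt(((y - ym) ** 2).sum())
    for perm in itertools.permutations(range(len(yr))):
        yp = (y[list(perm)] - ym) / ss
        vals.append(abs(float(x @ yp)))
    return np.sort(np.array(vals))


def spearman_assoc(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman correlation with a two-sided p-value.

    Exact p by enumeration of all rank permutations for n <= 8 (this
    matters: at the 6-7 producer scale of paired fermentations the
    t-approximation is anticonservative); t-distribution approximation
    for larger n.  A constant vector makes rho undefined: (nan, nan) is
    returned and callers must exclude the pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise ValueError("need paired vectors of length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    xr, yr = rankdata(x), rankdata(y)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    rho = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    if n <= exact_max_n:
        dist = _exact_abs_rho_distribution(tuple(sorted(xr)), tuple(sorted(yr)))
        hits = int((dist >= abs(rho) - 1e-12).sum())
        p = hits / len(dist)
    else:
        from scipy.stats import t as t_dist

        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * t_dist.sf(abs(t), n - 2))
    return rho, p


def build_network(
    phage_matrix: pd.DataFrame,
    host_matrix: pd.DataFrame,
    metadata: SampleMetadata,
    config: PipelineConfig,
    spacer_hits: list[SpacerHit] | None = None,
    host_predictions: dict[str, list[tuple[str, float, float]]] | None = None,
    mode: str = "starter_vs_cheese",
    stage: str = "starter",
) -> list[InteractionEdge]:
    """Assemble the thresholded phage-host interaction network.

    In ``starter_vs_cheese`` mode each producer contributes one point:
    the phage's normalized abundance in the producer's starter against
    the host's normalized abundance in the matching cheese (phages in
    the starter are expected to depress their host during production).
    In ``same_stage`` mode the matched samples of one stage are used.
    A pair gains ``correlation`` evidence iff Spearman rho <= rho_max
    and p <= p_max; CRISPR spacer hits and top-ranked significant
    Markov predictions attach as independent evidence.  Edges carry at
    least one evidence type and are sorted by (phage_id, host_id).
    """
    if phage_matrix.shape[0] == 0 or host_matrix.shape[0] == 0:
        return []
    if mode == "starter_vs_cheese":
        pairs = metadata.producer_pairs()
        keep = [
            i
            for i, (s, c) in enumerate(zip(pairs["starter"], pairs["cheese"]))
            if s in phage_matrix.columns and c in host_matrix.columns
        ]
        phage_cols = [pairs["starter"].iloc[i] for i in keep]
        host_cols = [pairs["cheese"].iloc[i] for i in keep]
    elif mode == "same_stage":
        samples = [
            s
            for s in metadata.samples(stage)
            if s in phage_matrix.columns and s in host_matrix.columns
        ]
        phage_cols = host_cols = samples
    else:
        raise ValueError(f"unknown mode: {mode}")
    if len(phage_cols) < 4:
        raise ValueError(
            f"need >= 4 paired producers/samples for correlations (got {len(phage_cols)})"
        )
    crispr_pairs: set[tuple[str, str]] = set()
    for hit in spacer_hits or []:
        crispr_pairs.add((hit.votu_id, hit.host_id))
    markov_pairs: set[tuple[str, str]] = set()
    for phage_id, ranking in (host_predictions or {}).items():
        if ranking:
            top_host, _, top_p = ranking[0]
            if top_p <= config.p_max:
                markov_pairs.add((phage_id, top_host))
    edges: list[InteractionEdge] = []
    for phage_id in phage_matrix.index:
        x = phage_matrix.loc[phage_id, phage_cols].to_numpy(dtype=float)
        for host_id in host_matrix.index:
            y = host_matrix.loc[host_id, host_cols].to_numpy(dtype=float)
            evidence: list[str] = []
            rho = p = float("nan")
            if not (np.all(x == x[0]) or np.all(y == y[0])):
                rho, p = spearman_assoc(x, y)
                if rho <= config.rho_max and p <= config.p_max:
                    evidence.append("correlation")
            if (phage_id, host_id) in crispr_pairs:
                evidence.append("crispr")
            if (phage_id, host_id) in markov_pairs:
                evidence.append("markov")
            if evidence:
                edges.append(InteractionEdge(phage_id, host_id, rho, p, evidence))
    edges.sort(key=lambda e: (e.phage_id, e.host_id))
    return edges
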
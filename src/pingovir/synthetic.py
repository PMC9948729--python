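"""Synthetic phage-host community generator with a ground-truth ledger.

Emulates the data shape of a paired starter/cheese virome survey:
~7 producers sampled at two stages, a phage catalog containing circular
(terminal-direct-repeat) and temperate members plus non-viral decoy
contigs, bacterial host genomes carrying CRISPR arrays whose spacers
are copied from catalog phages, abundance matrices with planted
negative phage-host couplings, and per-base depth profiles with
partial-breadth artifacts.

Every planted artifact — circularity, temperate flags, spacer
provenance, infection couplings, breadth dropouts, decoys — is recorded
in a :class:`GroundTruth` ledger, so each downstream inference stage
can be scored exactly without any external data.

Predation is modeled as rank-based multiplicative attenuation: for a
planted coupling (phage v, host h, beta), the host's log-normal
baseline in producer p is multiplied by exp(-beta * rank_norm(V_vp)),
where rank_norm is the phage's abundance rank across producers scaled
to [0, 1].  This plants exactly the monotone negative association a
co-abundance screen is meant to detect, with beta controlling effect
size; beta = 0 yields independence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ContigRecord, SampleMetadata, write_sequences, write_matrix, write_metadata
from .quant import DepthProfile, write_depth_profiles
from .triage import EvidenceRecord, write_evidence

__all__ = [
    "CommunityDesign",
    "GroundTruth",
    "SyntheticCommunity",
    "generate_phage_genomes",
    "generate_host_genomes",
    "simulate_abundances",
    "plant_dropouts",
    "simulate_depth_profiles",
    "emit_evidence_table",
    "generate_community",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
READ_LEN = 150  # nominal read length used to convert counts to depth


@dataclass
class CommunityDesign:
    """Study-condition knobs of the generator (defaults are the
    conditions the pipeline is exercised under)."""

    n_producers: int = 7
    n_phage: int = 30
    n_hosts: int = 8
    phage_len_range: tuple[int, int] = (5_000, 60_000)
    host_len_range: tuple[int, int] = (40_000, 80_000)
    decoy_len_range: tuple[int, int] = (1_500, 10_000)
    circular_fraction: float = 0.2
    temperate_fraction: float = 0.1
    decoy_fraction: float = 0.4        # decoys per phage, rounded
    coupling_beta: float = 8.0         # strength of planted predation
    lognormal_sigma: float = 0.2       # abundance noise (log scale)
    mutation_rate: float = 0.0         # per-base substitutions in spacer copies
    n_planted_edges: int | None = None  # default: min(n_phage, n_hosts)
    n_false_negatives: int = 0         # true phages planted with no passing evidence
    dropout_fraction: float = 0.08     # (contig, sample) pairs given partial breadth
    arrays_per_host: tuple[int, int] = (0, 5)
    repeat_len_range: tuple[int, int] = (24, 40)
    spacer_len_range: tuple[int, int] = (26, 40)
    tr_min_len: int = 20               # circular phages carry a 2*tr_min_len repeat
    library_size: int = 100_000
    min_contig_len: int = 1000

    @property
    def n_decoys(self) -> int:
        return round(self.decoy_fraction * self.n_phage)

    def validate(self) -> "CommunityDesign":
        for name in ("circular_fraction", "temperate_fraction", "mutation_rate", "dropout_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_producers < 3:
            raise ValueError("n_producers must be >= 3 for any correlation analysis")
        if self.coupling_beta < 0:
            raise ValueError(
                "coupling_beta must be >= 0: predation direction is fixed; "
                "anticorrelation emerges on ranks, it is not imposed"
            )
        if self.phage_len_range[0] < self.min_contig_len:
            raise ValueError("phage_len_range lower bound below min_contig_len")
        return self


@dataclass
class GroundTruth:
    """Ledger of everything the generator planted."""

    circular_ids: set[str] = field(default_factory=set)
    temperate_ids: set[str] = field(default_factory=set)
    decoy_ids: set[str] = field(default_factory=set)
    false_negative_ids: set[str] = field(default_factory=set)
    planted_edges: list[tuple[str, str, float]] = field(default_factory=list)
    spacer_provenance: list[tuple[str, int, int, str, int]] = field(default_factory=list)
    dropout_contigs: set[tuple[str, str]] = field(default_factory=set)
    evidence_criteria: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = {
            "circular_ids": sorted(self.circular_ids),
            "temperate_ids": sorted(self.temperate_ids),
            "decoy_ids": sorted(self.decoy_ids),
            "false_negative_ids": sorted(self.false_negative_ids),
            "planted_edges": self.planted_edges,
            "spacer_provenance": self.spacer_provenance,
            "dropout_contigs": sorted(self.dropout_contigs),
            "evidence_criteria": self.evidence_criteria,
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            circular_ids=set(data["circular_ids"]),
            temperate_ids=set(data["temperate_ids"]),
            decoy_ids=set(data["decoy_ids"]),
            false_negative_ids=set(data["false_negative_ids"]),
            planted_edges=[tuple(e) for e in data["planted_edges"]],
            spacer_provenance=[tuple(s) for s in data["spacer_provenance"]],
            dropout_contigs={tuple(d) for d in data["dropout_contigs"]},
            evidence_criteria={k: list(v) for k, v in data["evidence_criteria"].items()},
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# genomes

def generate_phage_genomes(
    design: CommunityDesign, seed: int
) -> tuple[list[ContigRecord], GroundTruth]:
    """I.i.d. uniform ACGT phage backbones.

    Circular phages get their first ``2*tr_min_len`` bases copied to the
    sequence end (a terminal direct repeat); the counts of circular and
    temperate members equal the rounded design fractions exactly.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    n = design.n_phage
    ids = [f"phage_{i:04d}" for i in range(n)]
    n_circ = round(design.circular_fraction * n)
    n_temp = round(design.temperate_fraction * n)
    circular = set(rng.choice(n, size=n_circ, replace=False).tolist())
    temperate = set(rng.choice(n, size=n_temp, replace=False).tolist())
    records = []
    tr = 2 * design.tr_min_len
    for i, pid in enumerate(ids):
        length = int(rng.integers(design.phage_len_range[0], design.phage_len_range[1] + 1))
        seq = _random_seq(rng, length)
        if i in circular:
            seq = seq + seq[:tr]
            truth.circular_ids.add(pid)
        if i in temperate:
            truth.temperate_ids.add(pid)
        records.append(ContigRecord(pid, seq))
    return records, truth


def _plant_array(
    rng: np.random.Generator,
    design: CommunityDesign,
    phages: list[ContigRecord],
    host_id: str,
    array_index: int,
    truth: GroundTruth,
) -> tuple[str, list[str]]:
    """Build one CRISPR array string R (S R) x k and record provenance."""
    rep_len = int(rng.integers(design.repeat_len_range[0], design.repeat_len_range[1] + 1))
    repeat = _random_seq(rng, rep_len)
    k = int(rng.integers(3, 7))  # repeats per array
    eligible = [p for p in phages if p.length >= design.spacer_len_range[1]]
    if not eligible:
        raise ValueError("no phage long enough to donate spacers")
    spacers: list[str] = []
    for spacer_index in range(k - 1):
        while True:
            src = eligible[int(rng.integers(len(eligible)))]
            s_len = int(rng.integers(design.spacer_len_range[0], design.spacer_len_range[1] + 1))
            offset = int(rng.integers(0, src.length - s_len + 1))
            spacer = src.seq[offset : offset + s_len]
            if design.mutation_rate > 0:
                arr = np.frombuffer(spacer.encode(), dtype=np.uint8).copy()
                hit = rng.random(s_len) < design.mutation_rate
                for j in np.flatnonzero(hit):
                    choices = _BASES[_BASES != arr[j]]
                    arr[j] = rng.choice(choices)
                spacer = arr.tobytes().decode()
            if spacer not in spacers:
                break
        spacers.append(spacer)
        truth.spacer_provenance.append((host_id, array_index, spacer_index, src.id, offset))
    parts = [repeat]
    for spacer in spacers:
        parts.append(spacer)
        parts.append(repeat)
    return "".join(parts), spacers


def _break_tie_base(rng: np.random.Generator, forbidden: str) -> str:
    choices = [b for b in "ACGT" if b != forbidden]
    return choices[int(rng.integers(3))]


def generate_host_genomes(
    design: CommunityDesign,
    phages: list[ContigRecord],
    seed: int,
    truth: GroundTruth | None = None,
) -> tuple[list[ContigRecord], GroundTruth]:
    """Host genomes with planted CRISPR arrays.

    Arrays are R (S R) x k with identical repeat copies and spacers
    copied from random phage windows (per-base substitution probability
    ``mutation_rate``).  The random bases flanking each array are forced
    to break any accidental repeat extension, so the planted repeat is
    exactly the maximal one.
    """
    if not phages:
        raise ValueError("phage set must be nonempty")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else GroundTruth()
    records = []
    for h in range(design.n_hosts):
        host_id = f"host_{h:03d}"
        length = int(rng.integers(design.host_len_range[0], design.host_len_range[1] + 1))
        n_arrays = int(rng.integers(design.arrays_per_host[0], design.arrays_per_host[1] + 1))
        segments: list[str] = []
        consumed = 0
        for a in range(n_arrays):
            pad = _random_seq(rng, max(300, length // (n_arrays + 1) - 120 * a))
            array, spacer_strs = _plant_array(rng, design, phages, host_id, a, truth)
            # break accidental left extension: the base before the first repeat
            last_bases = {s[-1] for s in spacer_strs}
            if len(last_bases) == 1 and pad[-1] in last_bases:
                pad = pad[:-1] + _break_tie_base(rng, pad[-1])
            segments.append(pad)
            segments.append(array)
            # break accidental right extension: the base after the last repeat
            first_bases = {s[0] for s in spacer_strs}
            tail_base = _random_seq(rng, 1)
            if len(first_bases) == 1 and tail_base in first_bases:
                tail_base = _break_tie_base(rng, tail_base)
            segments.append(tail_base)
            consumed += len(pad) + len(array) + 1
        if consumed < length:
            segments.append(_random_seq(rng, length - consumed))
        records.append(ContigRecord(host_id, "".join(segments)))
    return records, truth


# ---------------------------------------------------------------------------
# abundances

def simulate_abundances(
    design: CommunityDesign, truth: GroundTruth, seed: int,
    phage_ids: list[str] | None = None, host_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SampleMetadata]:
    """Paired starter/cheese count matrices with planted couplings.

    Phage abundance is drawn once per (phage, producer) — the cheese
    inherits its starter's phage load — while host baselines are drawn
    per (host, producer, stage).  For each planted edge the host is
    attenuated by exp(-beta * rank_norm(V)).  Counts are scaled to a
    target library size per sample and floored to integers, so the
    breadth rule rather than sampling noise dominates masking tests.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    phage_ids = phage_ids or [f"phage_{i:04d}" for i in range(design.n_phage)]
    host_ids = host_ids or [f"host_{h:03d}" for h in range(design.n_hosts)]
    for v, h, beta in truth.planted_edges:
        if v not in set(phage_ids) or h not in set(host_ids):
            raise ValueError(f"planted edge ({v}, {h}) references unknown ids")
        if beta < 0:
            raise ValueError("planted edge beta must be >= 0")
    producers = [f"P{i + 1:02d}" for i in range(design.n_producers)]
    sigma = design.lognormal_sigma
    mu_v = rng.uniform(2.0, 6.0, size=len(phage_ids))
    mu_h = rng.uniform(4.0, 8.0, size=len(host_ids))
    # phage abundance per producer (shared by both stages)
    v_abund = np.exp(rng.normal(mu_v[:, None], sigma, size=(len(phage_ids), len(producers))))
    rank_norm = np.apply_along_axis(
        lambda row: (rankdata(row) - 1) / (len(row) - 1), 1, v_abund
    )
    stages = [("starter", "S"), ("cheese", "C")]
    sample_ids = [f"{p}{code}" for p in producers for _, code in stages]
    h_cols = {}
    v_cols = {}
    edge_by_host: dict[str, list[tuple[int, float]]] = {}
    idx_of_phage = {pid: i for i, pid in enumerate(phage_ids)}
    for v, h, beta in truth.planted_edges:
        edge_by_host.setdefault(h, []).append((idx_of_phage[v], beta))
    for pi, producer in enumerate(producers):
        for stage, code in stages:
            sample = f"{producer}{code}"
            h_base = np.exp(rng.normal(mu_h, sigma))
            for hi, host in enumerate(host_ids):
                for v_idx, beta in edge_by_host.get(host, []):
                    h_base[hi] *= np.exp(-beta * rank_norm[v_idx, pi])
            h_cols[sample] = h_base
            v_cols[sample] = v_abund[:, pi]
    def _to_counts(cols: dict, index: list[str]) -> pd.DataFrame:
        df = pd.DataFrame(cols, index=index)[sample_ids]
        scaled = df / df.sum(axis=0) * design.library_size
        return np.floor(scaled).astype(int)
    counts_phage = _to_counts(v_cols, phage_ids)
    counts_host = _to_counts(h_cols, host_ids)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "producer_id": [s[:-1] for s in sample_ids],
                "stage": ["starter" if s.endswith("S") else "cheese" for s in sample_ids],
                "pair_id": [s[:-1] for s in sample_ids],
            }
        )
    )
    return counts_phage, counts_host, meta


def plant_dropouts(
    counts: pd.DataFrame, design: CommunityDesign, truth: GroundTruth, seed: int
) -> GroundTruth:
    """Choose (contig, sample) pairs with positive counts to receive
    partial-breadth depth profiles."""
    rng = np.random.default_rng(seed)
    positive = [
        (str(c), str(s)) for c in counts.index for s in counts.columns if counts.at[c, s] > 0
    ]
    n_drop = round(design.dropout_fraction * len(positive))
    chosen = rng.choice(len(positive), size=n_drop, replace=False)
    truth.dropout_contigs.update(positive[i] for i in chosen)
    return truth


def simulate_depth_profiles(
    counts: pd.DataFrame,
    contig_lengths: dict[str, int],
    truth: GroundTruth,
    seed: int,
) -> list[DepthProfile]:
    """Depth profiles consistent with the count matrix.

    Non-dropout pairs with positive counts are covered at >= 1x over at
    least 90% of positions; dropout pairs get a covered fraction drawn
    uniformly from [0.30, 0.70], guaranteed below the 0.75 breadth
    threshold.  Zero counts yield an empty (all-zero) profile.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for contig in counts.index:
        if contig not in contig_lengths:
            raise ValueError(f"unknown contig id in counts: {contig}")
        length = contig_lengths[contig]
        for sample in counts.columns:
            count = int(counts.at[contig, sample])
            if count == 0:
                profiles.append(DepthProfile(str(contig), str(sample), length, []))
                continue
            if (str(contig), str(sample)) in truth.dropout_contigs:
                frac = rng.uniform(0.30, 0.70)
            else:
                frac = rng.uniform(0.90, 1.0)
            covered = max(1, int(round(frac * length)))
            start = int(rng.integers(0, length - covered + 1))
            depth = max(1.0, count * READ_LEN / length)
            profiles.append(
                DepthProfile(str(contig), str(sample), length, [(start, start + covered, depth)])
            )
    return profiles


# ---------------------------------------------------------------------------
# evidence

def emit_evidence_table(
    truth: GroundTruth,
    phages: list[ContigRecord],
    decoys: list[ContigRecord],
    seed: int,
) -> list[EvidenceRecord]:
    """Evidence rows emulating external detectors and homology searches.

    Every true phage not planted as a false negative satisfies at least
    one inclusion criterion: viral-orthologous-group ORF hits (>= 3)
    with probability 0.8, otherwise a detector flag or a qualifying
    reference alignment.  Decoys fail all four criteria and carry an
    rRNA flag half the time.  The ledger records the criteria each
    contig is expected to satisfy (circularity included).
    """
    ids = [p.id for p in phages] + [d.id for d in decoys]
    if len(set(ids)) != len(ids):
        raise ValueError("phage and decoy ids must be unique")
    rng = np.random.default_rng(seed)
    records = []
    generic = ["terminase", "capsid protein", "tail protein", "endolysin", "holin"]
    for p in phages:
        rec = EvidenceRecord(contig_id=p.id)
        expected: list[str] = []
        if p.id in truth.false_negative_ids:
            rec.pvog_orf_hits = int(rng.integers(0, 3))
        elif rng.random() < 0.8:
            rec.pvog_orf_hits = int(rng.integers(3, 15))
            expected.append("orf_hits")
        elif rng.random() < 0.5:
            rec.detector_flag = True
            rec.pvog_orf_hits = int(rng.integers(0, 3))
            expected.append("detector")
        else:
            rec.pvog_orf_hits = int(rng.integers(0, 3))
            rec.ref_evalue = 10.0 ** float(rng.uniform(-40, -12))
            rec.ref_qcov = float(rng.uniform(0.91, 1.0))
            rec.ref_identity = float(rng.uniform(55.0, 99.0))
            expected.append("ref_alignment")
        if p.id in truth.circular_ids:
            expected.append("circular")
        rec.annotations = list(rng.choice(generic, size=2, replace=False))
        if p.id in truth.temperate_ids:
            rec.annotations.append("integrase")
        truth.evidence_criteria[p.id] = sorted(expected)
        records.append(rec)
    for d in decoys:
        rec = EvidenceRecord(
            contig_id=d.id,
            pvog_orf_hits=int(rng.integers(0, 3)),
            rrna_flag=bool(rng.random() < 0.5),
        )
        if rng.random() < 0.3:  # non-qualifying alignment (identity below 50%)
            rec.ref_evalue = 10.0 ** float(rng.uniform(-15, -11))
            rec.ref_qcov = float(rng.uniform(0.91, 1.0))
            rec.ref_identity = float(rng.uniform(20.0, 45.0))
        rec.annotations = ["hypothetical protein"]
        truth.evidence_criteria[d.id] = []
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SyntheticCommunity:
    design: CommunityDesign
    truth: GroundTruth
    phages: list[ContigRecord]
    hosts: list[ContigRecord]
    decoys: list[ContigRecord]
    evidence: list[EvidenceRecord]
    counts_phage: pd.DataFrame
    counts_host: pd.DataFrame
    metadata: SampleMetadata
    depth_profiles: list[DepthProfile]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sequences(self.phages, outdir / "phages.fasta")
        write_sequences(self.hosts, outdir / "hosts.fasta")
        write_sequences(self.decoys, outdir / "decoys.fasta")
        write_evidence(self.evidence, outdir / "evidence.tsv")
        write_matrix(self.counts_phage, outdir / "counts_phage.tsv")
        write_matrix(self.counts_host, outdir / "counts_host.tsv")
        write_metadata(self.metadata, outdir / "metadata.tsv")
        write_depth_profiles(self.depth_profiles, outdir / "depth.tsv")
        self.truth.to_json(outdir / "truth.json")


def generate_community(design: CommunityDesign, seed: int) -> SyntheticCommunity:
    """Run the full generator: genomes, arrays, abundances, depth,
    evidence — all pure functions of (design, seed)."""
    design.validate()
    phages, truth = generate_phage_genomes(design, seed)
    hosts, truth = generate_host_genomes(design, phages, seed + 1, truth)
    # planted predation couplings: phage i preys on host i
    n_edges = design.n_planted_edges
    if n_edges is None:
        n_edges = min(design.n_phage, design.n_hosts)
    for i in range(n_edges):
        truth.planted_edges.append(
            (phages[i % len(phages)].id, hosts[i % len(hosts)].id, design.coupling_beta)
        )
    # false negatives must be non-circular (circularity is intrinsic evidence)
    rng = np.random.default_rng(seed + 2)
    non_circular = [p.id for p in phages if p.id not in truth.circular_ids]
    if design.n_false_negatives > len(non_circular):
        raise ValueError("not enough non-circular phages to plant false negatives")
    if design.n_false_negatives:
        chosen = rng.choice(len(non_circular), size=design.n_false_negatives, replace=False)
        truth.false_negative_ids.update(non_circular[i] for i in chosen)
    decoys = []
    rng_d = np.random.default_rng(seed + 3)
    for i in range(design.n_decoys):
        length = int(rng_d.integers(design.decoy_len_range[0], design.decoy_len_range[1] + 1))
        decoys.append(ContigRecord(f"decoy_{i:03d}", _random_seq(rng_d, length)))
    truth.decoy_ids = {d.id for d in decoys}
    counts_phage, counts_host, metadata = simulate_abundances(
        design, truth, seed + 4, [p.id for p in phages], [h.id for h in hosts]
    )
    plant_dropouts(counts_phage, design, truth, seed + 5)
    lengths = {p.id: p.length for p in phages}
    depth = simulate_depth_profiles(counts_phage, lengths, truth, seed + 6)
    evidence = emit_evidence_table(truth, phages, decoys, seed + 7)
    return SyntheticCommunity(
        design, truth, phages, hosts, decoys, evidence,
        counts_phage, counts_host, metadata, depth,
    )
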
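"""Pipeline configuration.

All numeric thresholds used anywhere in the pipeline live in a single
:class:`PipelineConfig` so that a run is fully described by one flat
key/value document plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
import yaml

__all__ = ["PipelineConfig", "load_config", "dump_config"]

# bound spec per field: (low, high, low_inclusive, high_inclusive)
_FRACTION = (0.0, 1.0, True, True)
_PERCENT = (0.0, 100.0, True, True)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its default.

    Units: ``*_len`` fields are nucleotides, ``*_identity*`` /
    ``votu_ani_min`` / ``votu_af_min`` / ``spacer_identity_min`` are
    percentages in [0, 100], remaining ``*_min``/``*_max`` ratio fields
    are fractions in [0, 1].
    """

    min_contig_len: int = 1000      # drop assembled contigs shorter than this
    dedupe_identity: float = 0.90   # redundancy removal: identity over ...
    dedupe_cov: float = 0.90        # ... this fraction of the shorter contig
    pvog_min_orfs: int = 3          # viral-orthologous-group ORF hits needed
    pvog_evalue_max: float = 1e-5
    ref_evalue_max: float = 1e-10   # reference-alignment inclusion rule
    ref_qcov_min: float = 0.90
    ref_identity_min: float = 0.50
    tr_min_len: int = 20            # terminal direct repeat => circular
    votu_ani_min: float = 95.0      # vOTU merge: ANI >= this ...
    votu_af_min: float = 85.0       # ... over alignment fraction > this
    breadth_min: float = 0.75       # mask counts when breadth < this
    depth_min: float = 1.0          # depth threshold for breadth
    shannon_log_base: float = 2.0
    rho_max: float = -0.8           # network edge: Spearman rho <= this
    p_max: float = 0.05             # ... and p <= this
    spacer_identity_min: float = 90.0
    spacer_qcov_min: float = 0.80
    markov_order: int = 3           # host k-mer model order
    n_permutations: int = 999
    rng_seed: int = 0
    # secondary switches (documented in the methods note)
    breadth_rule_inverted: bool = False  # zero only when breadth < 1 - breadth_min
    jsd_sqrt: bool = False               # use metric sqrt(JSD) for ordination
    crispr_repeat_identity_min: float = 100.0  # exact repeats by default

    def validate(self) -> "PipelineConfig":
        bounds: dict[str, tuple] = {
            "dedupe_identity": _FRACTION,
            "dedupe_cov": _FRACTION,
            "ref_qcov_min": _FRACTION,
            "ref_identity_min": _FRACTION,
            "breadth_min": _FRACTION,
            "spacer_qcov_min": _FRACTION,
            "votu_ani_min": _PERCENT,
            "votu_af_min": _PERCENT,
            "spacer_identity_min": _PERCENT,
            "crispr_repeat_identity_min": _PERCENT,
            "p_max": _FRACTION,
        }
        for name, (lo, hi, lo_inc, hi_inc) in bounds.items():
            v = getattr(self, name)
            ok = (v >= lo if lo_inc else v > lo) and (v <= hi if hi_inc else v < hi)
            if not ok:
                raise ValueError(
                    f"config field {name}={v!r} outside "
                    f"{'[' if lo_inc else '('}{lo}, {hi}{']' if hi_inc else ')'}"
                )
        if self.rho_max >= 0:
            raise ValueError("config field rho_max must be negative")
        if self.n_permutations < 99:
            raise ValueError("config field n_permutations must be >= 99")
        if self.min_contig_len < 1:
            raise ValueError("config field min_contig_len must be >= 1")
        if self.tr_min_len < 1:
            raise ValueError("config field tr_min_len must be >= 1")
        if not 1 <= self.markov_order <= 8:
            raise ValueError("config field markov_order must be in [1, 8]")
        return self


def load_config(path: str | Path | None) -> PipelineConfig:
    """Read a flat key/value YAML document into a validated config.

    An empty (or absent) file yields the defaults.  Unknown keys are
    errors, not warnings: a typo in a threshold name must never silently
    run the pipeline with defaults.
    """
    cfg = PipelineConfig()
    if path is None:
        return cfg.validate()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return cfg.validate()
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} is not a flat key: value document")
    known = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    for key, value in data.items():
        if key not in known:
            raise ValueError(f"unknown config key: {key}")
        if isinstance(value, dict) or isinstance(value, list):
            raise ValueError(f"config key {key} must be a scalar")
        ftype = known[key].type
        if ftype == "int" and not isinstance(value, bool):
            value = int(value)
        elif ftype == "float":
            value = float(value)
        setattr(cfg, key, value)
    return cfg.validate()


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write a config back out as the same flat document ``load_config`` reads."""
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False, default_flow_style=False)
    )
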
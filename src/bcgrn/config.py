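"""Pipeline configuration.

A single :class:`PipelineConfig` object carries every tunable of the
pipeline: the bootstrap ensemble size, the per-stage significance levels,
the permutation count of the chromosome-cooperation test, the random seed,
and the GO-term size window used by GPEA.  All stochastic stages derive
their randomness from ``rng_seed``, so a run with a fixed config is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Tunable parameters shared across pipeline stages.

    Parameters
    ----------
    bootstrap_count
        Number of bootstrap resamples B of the expression matrix used by
        the ensemble inference (default 100).
    edge_alpha
        Significance level of the per-gene mutual-information test inside
        each bootstrap network, Bonferroni-corrected over the gene count.
    ensemble_alpha
        Significance level of the binomial test that aggregates edge
        frequencies across the ensemble into the final network.
    gpea_alpha
        Level of the Bonferroni correction applied to gene-pair enrichment
        p-values.
    perm_E
        Number of gene-label permutations of the chromosome-cooperation
        test (the production default is 100,000).
    rng_seed
        Seed for every source of randomness in a pipeline run.
    term_size_min, term_size_max
        Inclusive size window for annotation terms entering GPEA
        (defaults 3 and 999, i.e. "larger than 2 and less than 1000").
    null_pool_size
        Minimum size of the pooled permutation null used to assign
        empirical p-values to mutual-information values.
    binomial_p0
        Optional override of the binomial aggregation test's null success
        probability; ``None`` uses the ensemble's mean edge frequency over
        the union of observed edges.
    """

    bootstrap_count: int = 100
    edge_alpha: float = 0.05
    ensemble_alpha: float = 0.05
    gpea_alpha: float = 0.05
    perm_E: int = 100_000
    rng_seed: int = 0
    term_size_min: int = 3
    term_size_max: int = 999
    null_pool_size: int = 100_000
    binomial_p0: float | None = None

    def __post_init__(self) -> None:
        for name in ("edge_alpha", "ensemble_alpha", "gpea_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1); got {a}")
        if self.bootstrap_count < 1:
            raise ValueError("bootstrap_count must be >= 1")
        if self.perm_E < 1:
            raise ValueError("perm_E must be >= 1")
        if self.term_size_min > self.term_size_max:
            raise ValueError("term_size_min must be <= term_size_max")
        if self.binomial_p0 is not None and not 0.0 < self.binomial_p0 < 1.0:
            raise ValueError("binomial_p0 must lie strictly in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a flat-key YAML file; absent keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
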
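"""Run configuration: every analysis constant as a named, overridable key.

Defaults are the study's operating values: genomewide and interaction test
levels, the Bonferroni-style per-coefficient level 0.0125 (= 0.05/4), the
marginal-t level 0.025, the Holm family level (0.1 for a shared-locus
triple), span-gap merging at 10 cM, locus matching/merging at 20 cM,
cross-age unification at 30 cM, and 1000 permutations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    n_perm: int = 1000
    alpha_genomewide: float = 0.05
    alpha_interaction_joint: float = 0.05
    alpha_interaction_coef: float = 0.0125
    alpha_marginal_t: float = 0.025
    holm_family_alpha: float = 0.05
    holm_triple_alpha: float = 0.1
    gap_max_cM: float = 10.0
    locus_match_cM: float = 20.0
    crossage_match_cM: float = 30.0
    pair_min_separation_cM: float = 20.0
    scan_step_cM: float = 1.0
    pair_scan_step_cM: float = 5.0
    trait_terms: dict = field(default_factory=dict)   # trait -> candidate terms

    def __post_init__(self):
        for name in ("alpha_genomewide", "alpha_interaction_joint",
                     "alpha_interaction_coef", "alpha_marginal_t",
                     "holm_family_alpha", "holm_triple_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
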
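"""Run configuration shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Tunable parameters of the discovery pipeline.

    Defaults follow the study conditions: TFs qualify with at least 30
    activated targets; conservation masking retains 10% of the DNA; de
    novo motif lengths are 6, 8 and 10; library enrichment p-values use
    10,000 label permutations and de novo p-values 100 full discovery
    permutations; networks are consensus over 100 bootstraps at
    p < 1e-7; the MI significance level is 5e-2 (Bonferroni-corrected
    over pairs) and the co-expression level 1e-4.
    """

    min_targets: int = 30
    coverage_fraction: float = 0.10
    motif_lengths: tuple = (6, 8, 10)
    library_permutations: int = 10000
    denovo_permutations: int = 100
    significance_alpha: float = 0.05
    bootstraps: int = 100
    consensus_alpha: float = 1e-7
    mi_alpha: float = 5e-2
    coexpr_alpha: float = 1e-4
    rng_seed: int = 0
    # less central knobs
    dpi_tolerance: float = 0.0
    min_pattern_species: int = 4
    n_background: int = 2000
    beam_width: int = 50
    seed_words: int = 500
    refine_max_iter: int = 100
    short_promoters: str = "drop"  # or "pad"

    def __post_init__(self) -> None:
        for name in ("significance_alpha", "consensus_alpha", "mi_alpha", "coexpr_alpha"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 < self.coverage_fraction < 1.0):
            raise ValueError("coverage_fraction must be in (0, 1)")
        if self.min_targets < 1:
            raise ValueError("min_targets must be >= 1")
        if self.bootstraps < 1:
            raise ValueError("bootstraps must be >= 1")
        self.motif_lengths = tuple(sorted(set(int(l) for l in self.motif_lengths)))
        if any(l < 4 for l in self.motif_lengths):
            raise ValueError("motif lengths must be >= 4")
        if self.short_promoters not in ("drop", "pad"):
            raise ValueError("short_promoters must be 'drop' or 'pad'")
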
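"""Configuration for the synthetic count-matrix generator."""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_CONDITIONS = ("astro_d1", "astro_d7", "mir124_d7", "mir124_isx9_d7")

#: Condition-activity archetypes. Values are multipliers of ``effect_log2fc``
#: applied to the latent regulator activity in each of the four conditions,
#: in DEFAULT_CONDITIONS order. The resulting mean-activity orderings realize
#: the five heatmap classes used downstream.
PATTERNS: dict[str, tuple[float, float, float, float]] = {
    "orange": (0.0, 0.0, 0.5, 1.0),     # isx9 > mir124 > astro
    "magenta": (0.0, 0.0, 1.0, 0.5),    # mir124 > isx9 > astro
    "red": (0.0, 0.0, 0.0, 1.0),        # isx9 alone up
    "blue": (1.0, 1.0, 0.5, 0.0),       # astro > mir124 > isx9
    "turquoise": (1.0, 1.0, 0.0, 0.5),  # astro > isx9 > mir124
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted-regulon count simulator.

    NB dispersion follows variance = mu + alpha * mu**2; per-gene alphas are
    drawn log-normally around `dispersion`. `coupling` scales how strongly a
    target's mean tracks its regulator's latent activity (0 = independent);
    `target_noise_sd` adds private log2-scale noise per target and sample, so
    indirect (condition-driven) cross-regulon dependence stays below the
    direct regulator-target signal.
    """

    n_tfs: int = 10
    targets_per_tf: int = 30
    n_nontarget_genes: int = 40
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    reps_per_condition: int = 4
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    effect_log2fc: float = 1.7
    mode_neg_fraction: float = 0.3
    coupling: float = 1.0
    activity_sd: float = 0.7
    target_noise_sd: float = 0.5
    overlap_fraction: float = 0.0
    seed: int = 0
    pattern_cycle: tuple[str, ...] = field(default=tuple(PATTERNS))

    def __post_init__(self) -> None:
        # YAML round-trips deliver lists; normalize to the frozen tuple form
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "pattern_cycle", tuple(self.pattern_cycle))
        for name in ("n_tfs", "targets_per_tf", "reps_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_nontarget_genes < 0:
            raise ValueError("n_nontarget_genes must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0.0 <= self.mode_neg_fraction <= 1.0:
            raise ValueError("mode_neg_fraction must be in [0, 1]")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.activity_sd < 0:
            raise ValueError("activity_sd must be >= 0")
        if self.target_noise_sd < 0:
            raise ValueError("target_noise_sd must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if len(self.conditions) != len(DEFAULT_CONDITIONS):
            raise ValueError("conditions must list exactly four labels")
        unknown = set(self.pattern_cycle) - set(PATTERNS)
        if unknown:
            raise ValueError(f"pattern_cycle has unknown labels: {sorted(unknown)}")

    @property
    def n_genes(self) -> int:
        return self.n_tfs * (1 + self.targets_per_tf) + self.n_nontarget_genes

    @property
    def n_samples(self) -> int:
        return len(self.conditions) * self.reps_per_condition
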
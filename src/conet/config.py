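"""Configuration objects and validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class ConfigurationError(ValueError):
    """Raised when a configuration value violates an invariant.

    The offending field name is stored in :attr:`field_name` and included in
    the message.
    """

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


_PROBABILITY_FIELDS = (
    "marginal_dhs_rate",
    "module_activity_rate",
    "flip_noise",
    "motif_base_rate",
    "driver_motif_rate",
    "strong_fraction",
    "contact_within_module_rate",
    "contact_background_rate",
    "module_strong_rate_small",
    "module_strong_rate_large",
    "label_fidelity",
    "ambiguous_fraction",
)

_POSITIVE_COUNT_FIELDS = (
    "n_cell_types",
    "n_chromosomes",
    "chrom_length",
    "n_enhancers",
    "n_motifs",
    "n_terms",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic genome generator.

    Defaults produce a small genome (2,000 enhancers, 37 cell types) that a
    laptop simulates in seconds while retaining the statistical structure the
    analysis assumes: cell-type marginal accessibility rates, a
    distance-decaying accessibility autocorrelation along each chromosome,
    planted co-active enhancer modules with shared driver motifs,
    module-coupled target-gene expression, strength labels, within-module
    spatial contacts and shared annotation terms.
    """

    n_cell_types: int = 37
    n_chromosomes: int = 4
    chrom_length: int = 50_000_000
    n_enhancers: int = 2_000
    marginal_dhs_rate: float = 0.3
    autocorr_decay_length: float = 50_000.0
    n_modules: int = 10
    module_size: int = 8
    module_activity_rate: float = 0.5
    flip_noise: float = 0.05
    n_motifs: int = 150
    motif_base_rate: float = 0.2
    driver_motifs_per_module: int = 2
    driver_motif_rate: float = 0.9
    expression_noise_sd: float = 0.3
    strong_fraction: float = 0.5
    contact_within_module_rate: float = 0.5
    contact_background_rate: float = 1e-4
    n_terms: int = 50
    seed: int = 0

    # Secondary knobs (sensible defaults; all optional).
    enhancer_length: int = 500
    min_spacing: int = 2_000
    n_expression_cell_types: int = 15
    gene_offset_max: int = 400
    module_spacing: int | None = None  # compress module runs to this spacing
    small_module_cutoff: int = 6
    module_strong_rate_small: float = 0.8
    module_strong_rate_large: float = 0.15
    label_fidelity: float = 0.9
    ambiguous_fraction: float = 0.05
    term_background_size: int = 20

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(name, f"probability {value!r} outside [0, 1]")
        for name in _POSITIVE_COUNT_FIELDS:
            value = getattr(self, name)
            if value < 1:
                raise ConfigurationError(name, f"count must be >= 1, got {value!r}")
        if self.module_size < 2:
            raise ConfigurationError("module_size", "module size must be >= 2")
        if self.n_modules < 0:
            raise ConfigurationError("n_modules", "must be >= 0")
        if self.n_modules * self.module_size > self.n_enhancers:
            raise ConfigurationError(
                "n_modules",
                f"n_modules * module_size = {self.n_modules * self.module_size} "
                f"exceeds n_enhancers = {self.n_enhancers}",
            )
        per_chrom = -(-self.n_enhancers // self.n_chromosomes)  # ceil
        if self.chrom_length <= per_chrom * self.min_spacing:
            raise ConfigurationError(
                "chrom_length",
                f"too short to place {per_chrom} enhancers per chromosome "
                f"at minimum spacing {self.min_spacing}",
            )
        if self.autocorr_decay_length < 0:
            raise ConfigurationError("autocorr_decay_length", "must be >= 0")
        if self.expression_noise_sd < 0:
            raise ConfigurationError("expression_noise_sd", "must be >= 0")
        if self.driver_motifs_per_module * max(self.n_modules, 1) > self.n_motifs:
            raise ConfigurationError(
                "driver_motifs_per_module",
                "not enough motifs for the requested number of drivers",
            )
        if self.module_spacing is not None and self.module_spacing < self.min_spacing:
            raise ConfigurationError(
                "module_spacing", "cannot be below min_spacing"
            )
        if self.n_expression_cell_types > self.n_cell_types:
            raise ConfigurationError(
                "n_expression_cell_types", "cannot exceed n_cell_types"
            )

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return SimulationConfig(**current)
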
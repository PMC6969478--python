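"""Generator configuration.

The defaults encode the study conditions of an anostracan (fairy shrimp)
larva elongating at 30 °C: three trunk Engrailed (En) stripes at hatch, one
new segment every 1.4 h, a first molt at 3.7 h that lengthens the growth
zone by ~2.5 cell diameters, a growth zone that shrinks as segments are
added while its anterior width (width A, the width of the newest En stripe)
stays constant, 1–4 % of growth-zone cells in mitosis with ~80 % of spindles
oriented along the anterior–posterior (AP) axis, pH3 marking ~2.4× more
mitoses than late-M nuclear morphology, and a tri-domain S-phase pattern
(synchronous band in the newest segment, clear anterior growth zone,
scattered posterior growth zone).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .errors import ConfigError

__all__ = ["GeneratorConfig"]


@dataclass
class GeneratorConfig:
    # -- staging clock -----------------------------------------------------
    interval_h: float = 1.4            # hours per new segment
    initial_stripes: int = 3           # trunk En stripes at hatch
    max_stripes: int = 17              # staging cap (thoracic+genital+abdominal)
    molt_time_h: float = 3.7           # first molt, hours post hatch
    molt_gz_gain_cells: float = 2.5    # GZ length gain (cells) at the molt

    # -- geometry ----------------------------------------------------------
    cell_diameter_um: float = 6.0      # mean nucleus spacing
    gz_length0_cells: float = 13.0     # GZ length at hatch, in cells
    widthA_cells: int = 22             # width at the last En stripe, in cells
    widthB_cells: int = 28             # width at the GZ/telson boundary, in cells
    gz_shrink_per_segment: float = 0.6     # GZ length loss per added segment (cells)
    gz_widthB_shrink_per_segment: float = 0.4  # width-B loss per added segment (cells)
    seg_length_cells_by_order: tuple = (4, 4, 4, 4, 4, 3, 3, 3, 3, 2, 2, 2, 2, 2)
    initial_seg_length_cells: int = 4  # length of the segments present at hatch
    telson_length_cells: int = 8
    head_length_um: float = 200.0      # head offset included in body length only
    seg_growth_per_stage: float = 0.1  # segment maturation growth per stage
    seg_growth_cap: float = 2.0        # maturation growth saturates at 2x
    constant_gz_mode: bool = False     # Artemia-like: GZ length maintained

    # -- cell-cycle labels -------------------------------------------------
    mitotic_fraction: float = 0.025    # GZ M-phase fraction (nuclear morphology)
    seg_mitotic_fraction: float = 0.05
    telson_mitotic_fraction: float = 0.01
    ph3_ratio: float = 2.4             # expected pH3 : nuclear-morphology count ratio
    ap_orientation_prob: float = 0.8   # P(GZ mitosis oriented along AP axis)
    seg_ap_orientation_prob: float = 0.25  # segmented mitoses are transverse-biased
    edu_scatter_frac: float = 0.35     # S-phase fraction, posterior GZ
    edu_clear_frac: float = 0.02       # S-phase fraction, anterior GZ (near 0)
    band_sync_frac: float = 0.98       # S-phase fraction, newest segment (near 1)
    seg_s_frac: float = 0.30           # S-phase fraction, older segments
    telson_s_frac: float = 0.05
    gz_anterior_frac: float = 0.4      # fraction of GZ length in the clear domain
    band_m_suppression: float = 0.1    # M-flag damping inside the synchronous band
    band_lateral_spill_prob: float = 0.0  # band spills into penultimate segment edges

    # -- observation noise -------------------------------------------------
    stage_noise_stripes: int = 1       # stripe-count noise, uniform on {-k..k}
    hatch_jitter_min: float = 15.0     # hatch-time uncertainty (collection interval)
    phase_jitter_frac: float = 1.0     # segmentation-cycle phase at hatch, U[0, f*interval)
    size_cv: float = 0.03              # per-larva overall size variation
    jitter_frac: float = 0.2           # lattice position jitter, fraction of spacing

    def validate(self) -> "GeneratorConfig":
        """Raise :class:`ConfigError` if any invariant is violated."""
        if self.interval_h <= 0:
            raise ConfigError("interval_h must be > 0")
        for name in ("initial_stripes", "max_stripes", "widthA_cells",
                     "widthB_cells", "telson_length_cells",
                     "initial_seg_length_cells"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.gz_length0_cells < 1:
            raise ConfigError("gz_length0_cells must be >= 1")
        if self.cell_diameter_um <= 0:
            raise ConfigError("cell_diameter_um must be > 0")
        if self.max_stripes < self.initial_stripes:
            raise ConfigError("max_stripes must be >= initial_stripes")
        if not self.seg_length_cells_by_order:
            raise ConfigError("seg_length_cells_by_order must be non-empty")
        if any(v < 1 for v in self.seg_length_cells_by_order):
            raise ConfigError("segment lengths must be >= 1 cell")
        probs = ("mitotic_fraction", "seg_mitotic_fraction",
                 "telson_mitotic_fraction", "ap_orientation_prob",
                 "seg_ap_orientation_prob", "edu_scatter_frac",
                 "edu_clear_frac", "band_sync_frac", "seg_s_frac",
                 "telson_s_frac", "gz_anterior_frac", "band_m_suppression",
                 "band_lateral_spill_prob", "jitter_frac")
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not (self.edu_clear_frac < self.edu_scatter_frac < self.band_sync_frac):
            raise ConfigError(
                "S-phase fractions must satisfy clear < scattered < band")
        if self.ph3_ratio <= 0:
            raise ConfigError("ph3_ratio must be > 0")
        for name in ("hatch_jitter_min", "phase_jitter_frac", "size_cv",
                     "gz_shrink_per_segment", "gz_widthB_shrink_per_segment",
                     "molt_gz_gain_cells", "seg_growth_per_stage"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.stage_noise_stripes < 0:
            raise ConfigError("stage_noise_stripes must be >= 0")
        return self

    def segment_base_length(self, order: int) -> int:
        """Length (cells) of the ``order``-th added segment (1-based).

        Orders past the configured list repeat the last entry.
        """
        seq = self.seg_length_cells_by_order
        return int(seq[min(order, len(seq)) - 1])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["seg_length_cells_by_order"] = list(self.seg_length_cells_by_order)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seg_length_cells_by_order" in data:
            data = dict(data)
            data["seg_length_cells_by_order"] = tuple(
                data["seg_length_cells_by_order"])
        return cls(**data).validate()
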
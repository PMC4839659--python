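"""Central threshold set shared by every pipeline stage.

All numeric screening constants live in one :class:`Thresholds` object so
a run is auditable from a single flat key/value file.  Unknown keys in a
config file are an error: thresholds drive the science and a silently
ignored typo is worse than a crash.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


class ConfigError(ValueError):
    """Malformed configuration file or threshold invariant violation."""


@dataclass(frozen=True)
class Thresholds:
    """Numeric screening constants for the whole pipeline.

    Interval fields are closed (inclusive at both ends) and expressed in
    nucleotides unless noted otherwise.
    """

    #: overall read length window retained after library construction
    read_len_min: int = 15
    read_len_max: int = 30
    #: mature-miRNA candidate length window
    mirna_len_min: int = 18
    mirna_len_max: int = 26
    #: piRNA candidate length window
    pirna_len_min: int = 26
    pirna_len_max: int = 30
    #: precursor window scan geometry
    window_min: int = 60
    window_max: int = 300
    window_step: int = 20
    #: hairpin energy screen: mfe must be < mfe_coeff * precursor_length
    mfe_coeff: float = -0.35
    #: hairpin curation limits in the mature region
    max_mismatch_mature: int = 4
    max_bulge_mature: int = 2
    max_bulge_len: int = 2
    min_paired_frac: float = 0.5
    #: duplex 3'-overhang length
    overhang: int = 2
    #: abundance screens
    min_abund_with_star: int = 3
    min_abund_no_star: int = 100
    #: plant-mode target prediction
    plant_max_mismatch: float = 3.0
    plant_max_upe: float = 30.0
    #: animal-mode target prediction (seed = positions 2-8 from the 5' end)
    animal_seed_start: int = 2
    animal_seed_end: int = 8
    animal_max_energy: float = -20.0
    #: ta-siRNA phasing
    phase_len: int = 21
    phase_window: int = 231
    phase_alpha: float = 0.001
    #: nat-siRNA minimum sense/antisense gene overlap
    nat_min_overlap: int = 25

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _check(cond: bool, key: str, msg: str) -> None:
            if not cond:
                raise ConfigError(f"threshold '{key}': {msg}")

        _check(self.read_len_min <= self.read_len_max, "read_len_min",
               "empty read length interval")
        _check(self.mirna_len_min <= self.mirna_len_max, "mirna_len_min",
               "empty miRNA length interval")
        _check(self.pirna_len_min <= self.pirna_len_max, "pirna_len_min",
               "empty piRNA length interval")
        _check(self.window_min <= self.window_max, "window_min",
               "window_min must be <= window_max")
        _check(self.window_step > 0, "window_step", "step must be > 0")
        _check(self.mfe_coeff < 0, "mfe_coeff", "must be negative")
        _check(self.phase_len > 0, "phase_len", "must be positive")
        _check(self.phase_window > 0 and self.phase_window % self.phase_len == 0,
               "phase_window",
               f"must be a positive multiple of phase_len ({self.phase_len})")
        _check(0.0 < self.phase_alpha < 1.0, "phase_alpha", "must be in (0,1)")
        _check(self.overhang >= 0, "overhang", "must be >= 0")
        _check(self.max_bulge_len >= 0, "max_bulge_len", "must be >= 0")
        _check(0.0 <= self.min_paired_frac <= 1.0, "min_paired_frac",
               "must be a fraction in [0,1]")
        _check(1 <= self.animal_seed_start <= self.animal_seed_end,
               "animal_seed_start", "invalid seed interval")

    # -- flat key/value round trip --------------------------------------

    def to_file(self, path: str | Path) -> None:
        """Write as ``key = value`` lines ('#' comments allowed on read)."""
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(Thresholds)}


def load_thresholds(path: str | Path | None = None) -> Thresholds:
    """Load thresholds from a flat key/value file; absent keys default.

    Parameters
    ----------
    path:
        Config file path, or None for all defaults.  The file format is
        one ``key = value`` per line; blank lines and ``#`` comments are
        ignored.  Unknown keys raise :class:`ConfigError`.
    """
    if path is None:
        return Thresholds()
    overrides: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in _FIELD_TYPES:
            raise ConfigError(f"{path}:{lineno}: unknown threshold key '{key}'")
        try:
            typ = _FIELD_TYPES[key]
            overrides[key] = int(value) if "int" in str(typ) else float(value)
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for '{key}': {value!r}") from exc
    return Thresholds(**overrides)
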
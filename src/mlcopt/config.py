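"""Package-wide defaults and logging setup.

Every tunable that more than one module touches lives here so that the CLI,
the library API and the tests agree on a single source of truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = ["Defaults", "DEFAULTS", "setup_logging"]


@dataclass(frozen=True)
class Defaults:
    """Default analysis parameters.

    Gamma criteria follow the common clinical QA convention:
    2 mm DTA, 2% dose difference with global normalization and a 10%
    low-dose threshold.
    """

    # gamma analysis
    dta_mm: float = 2.0
    dd_fraction: float = 0.02
    threshold_fraction: float = 0.10
    normalization: str = "global"
    upsample_factor: int = 10
    search_factor: float = 3.0

    # parameter grid box (mm, fraction)
    dlg_min: float = 0.0
    dlg_max: float = 2.5
    transmission_min: float = 0.0001
    transmission_max: float = 0.025

    # optimizer
    n_starts: int = 8
    dlg_tolerance_mm: float = 0.01
    transmission_tolerance: float = 0.0005
    cost_rtol: float = 1e-6
    near_optimal_band: float = 1e-4
    nonunique_span_steps: int = 3

    # simulator / measurement
    sweep_extent_mm: float = 60.0
    penumbra_sigma_mm: float = 2.0
    detector_pitch_mm: float = 5.0

    # deterministic DICOM UID root for reproducible file output
    uid_root: str = "1.2.826.0.1.3680043.10.1474."

    # one seed governs every stochastic step unless overridden
    seed: int = 0

    extras: dict = field(default_factory=dict)


DEFAULTS = Defaults()


def setup_logging(level: str = "INFO") -> logging.Logger:
    """Configure the package logger (idempotent)."""
    logger = logging.getLogger("mlcopt")
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level.upper())
    return logger
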
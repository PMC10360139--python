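"""Package-wide numeric settings.

All tolerances, truncation thresholds and optimizer seeds used by the
computational core live in one mutable settings object so that a single
instance can be passed around (or the module-level default mutated) instead
of scattering magic numbers through the code.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class NumericSettings:
    """Numeric conventions shared by the LQ core and the fitting machinery.

    Attributes
    ----------
    quad_rel_tol:
        Relative tolerance for adaptive quadrature cross-checks of the
        closed-form survival integrals.
    sf_truncation:
        Survival level below which the tail of a survival curve is treated
        as analytically negligible when a quadrature needs a finite upper
        limit.
    root_tol:
        Relative tolerance for iso-survival dose root finding (closed forms
        are exact; this bounds acceptable round-trip error).
    multistart_seed:
        Seed for the fixed multi-start list used by multi-modal candidate
        LET-function fits; fixing it makes grid searches reproducible
        bit-for-bit.
    n_multistart:
        Number of log-uniform starts for families with shape parameters
        (h, k or s).
    global_rbe_sigma:
        Default relative standard error assigned to a measured RBE value in
        chi-squared statistics when no covariance information is available.
    """

    quad_rel_tol: float = 1e-10
    sf_truncation: float = 1e-12
    root_tol: float = 1e-12
    multistart_seed: int = 20220728
    n_multistart: int = 16
    global_rbe_sigma: float = 0.10
    extra: dict = field(default_factory=dict)


#: Default settings instance used when callers do not supply their own.
DEFAULT = NumericSettings()
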
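"""Piecewise quadratic/linear ligament bundle mechanics.

A bundle produces tensile force only, along the straight origin-insertion
line: zero when slack, a quadratic toe region up to twice the linear strain
limit, then linear with stiffness ``k`` (N per unit strain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kneesim.errors import DomainError

#: Default linear strain limit; the standard toe-region value, uniform
#: across bundles and overridable per bundle.
DEFAULT_EPS_L = 0.03


@dataclass
class LigamentBundle:
    """One ligament bundle: attachments, stiffness and strain parameters.

    ``origin_body``/``insertion_body`` name the carrying rigid bodies;
    local points are in each body's reference coordinates (mm).  ``L0`` is
    the slack length, usually calibrated from the reference strain at full
    extension via :func:`slack_length_from_reference`.
    """

    name: str
    group: str
    k: float  # N per unit strain
    eps_r: float  # strain at full knee extension
    eps_l: float = DEFAULT_EPS_L
    origin_body: str = ""
    origin_point: np.ndarray | None = None
    insertion_body: str = ""
    insertion_point: np.ndarray | None = None
    L0: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise DomainError(f"{self.name}: stiffness must be >= 0")
        if self.eps_l <= 0:
            raise DomainError(f"{self.name}: linear strain limit must be > 0")
        if self.origin_point is not None:
            self.origin_point = np.asarray(self.origin_point, float).reshape(3)
        if self.insertion_point is not None:
            self.insertion_point = np.asarray(self.insertion_point, float).reshape(3)


#: (group, bundle, k N/strain, reference strain) for the 10 ligaments /
#: 22 bundles of the default knee model.
DEFAULT_BUNDLE_PARAMETERS: tuple[tuple[str, str, float, float], ...] = (
    ("ACL", "aACL", 5000.0, 0.06),
    ("ACL", "pACL", 5000.0, 0.10),
    ("PCL", "aPCL", 9000.0, -0.24),
    ("PCL", "pPCL", 9000.0, -0.03),
    ("LCL", "aLCL", 2000.0, 0.03),
    ("LCL", "mLCL", 2000.0, -0.05),
    ("LCL", "pLCL", 2000.0, 0.08),
    ("MCL", "aMCL", 2500.0, 0.04),
    ("MCL", "mMCL", 3000.0, 0.04),
    ("MCL", "pMCL", 2500.0, 0.04),
    ("MCL", "aDMCL", 1000.0, -0.18),
    ("MCL", "pDMCL", 1000.0, -0.04),
    ("MPFL", "sMPFL", 2000.0, 0.08),
    ("MPFL", "mMPFL", 2000.0, 0.08),
    ("MPFL", "iMPFL", 2000.0, 0.08),
    ("LPFL", "sLPFL", 2000.0, 0.06),
    ("LPFL", "mLPFL", 2000.0, 0.06),
    ("LPFL", "iLPFL", 2000.0, 0.06),
    ("PMC", "PMC", 2000.0, -0.04),
    ("POL", "POL", 1500.0, -0.18),
    ("ALL", "ALL", 2000.0, 0.05),
    ("PFL", "PFL", 2000.0, 0.05),
)


def default_bundle_table(eps_l: float = DEFAULT_EPS_L) -> list[LigamentBundle]:
    """The default 22-bundle (10-ligament) parameter set.

    Attachment sites are left empty; they are model/fixture configuration,
    not constants of the force law.
    """
    return [
        LigamentBundle(name=bundle, group=group, k=k, eps_r=eps_r, eps_l=eps_l)
        for group, bundle, k, eps_r in DEFAULT_BUNDLE_PARAMETERS
    ]


def slack_length_from_reference(length_at_full_extension: float, eps_r: float) -> float:
    """Slack length from the bundle length at full extension: L0 = L / (1 + eps_r)."""
    if length_at_full_extension <= 0:
        raise DomainError("length at full extension must be positive")
    if eps_r <= -1:
        raise DomainError("reference strain must exceed -1")
    return length_at_full_extension / (1.0 + eps_r)


def bundle_strain(current_length, L0):
    """Engineering strain (L - L0) / L0."""
    L0 = np.asarray(L0, float)
    if np.any(L0 <= 0):
        raise DomainError("slack length must be positive")
    return (np.asarray(current_length, float) - L0) / L0


def bundle_force(eps, k, eps_l=DEFAULT_EPS_L):
    """Tensile bundle force (N) for strain ``eps``.

    Zero when slack, quadratic toe ``k*eps^2 / (4*eps_l)`` for
    ``0 <= eps <= 2*eps_l``, linear ``k*(eps - eps_l)`` beyond; C0/C1
    continuous at the transition.  Vectorized over all arguments.
    """
    eps = np.asarray(eps, float)
    k = np.asarray(k, float)
    eps_l = np.asarray(eps_l, float)
    if np.any(eps_l <= 0):
        raise DomainError("linear strain limit must be positive")
    toe = 0.25 * k * eps**2 / eps_l
    linear = k * (eps - eps_l)
    out = np.where(eps > 2.0 * eps_l, linear, toe)
    out = np.where(eps < 0.0, 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out
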
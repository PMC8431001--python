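"""Two-solute hydration analysis: theoretical spectra, delta-N, shared/excess water.

For a peptide + osmolyte mixture at osmolyte mole fraction x (among the
solutes), the non-interacting reference is the intensity-weighted sum of the
pure-component affected spectra,

    N_theor = (1-x) N_p + x N_o
    eps_theor = [(1-x) N_p eps_p + x N_o eps_o] / N_theor

per mole of solute pair.  A deficit of affected water in the mixture
(delta_N = N_exp - N_theor < 0) signals *shared* water lying in both
hydration spheres at once; a surplus signals *excess* water perturbed only
when both solutes are present (including bridging water).

The experimentally affected water is decomposed by retaining as much
pure-solute affected water as the data allow: maximise
w_p (1-x) N_p + w_o x N_o over (w_p, w_o) in [0,1]^2 subject to the
remainder

    r(nu) = N_exp eps_exp - w_p (1-x) N_p eps_p - w_o x N_o eps_o

being non-negative (within a noise tolerance delta) at every wavenumber.
The remainder is the shared/excess spectrum, scaled by its water count
N_sh = N_exp - w_p (1-x) N_p - w_o x N_o.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .errors import DomainError, ValidationError
from .spectra import Spectrum

__all__ = [
    "TernaryInputs",
    "TernaryDecomposition",
    "theoretical_affected",
    "delta_N",
    "decompose_shared_excess",
    "denoised_decomposition",
]


@dataclass(frozen=True)
class TernaryInputs:
    """Pure-component and mixture affected spectra on the common grid."""

    eps_p: Spectrum
    N_p: float
    eps_o: Spectrum
    N_o: float
    x: float  # osmolyte mole fraction among solutes
    eps_exp: Spectrum
    N_exp: float  # per mole of solute pair at ratio x
    sigma_N_exp: float = 0.0
    sigma_N_theor: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.x <= 1.0):
            raise DomainError(f"x must be in [0, 1], got {self.x}")
        for name in ("N_p", "N_o", "N_exp"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        grid = self.eps_p.grid
        for s in (self.eps_o, self.eps_exp):
            if s.grid.shape != grid.shape or not np.allclose(s.grid, grid, atol=1e-9, rtol=0):
                raise ValidationError("all spectra must share the common grid")


@dataclass(frozen=True)
class TernaryDecomposition:
    """Theoretical reference, delta-N and the shared/excess split."""

    eps_theor: Spectrum
    N_theor: float
    delta_N: float
    w_p: float
    w_o: float
    eps_sh: Spectrum
    N_sh: float
    share_pct: float
    label: str  # shared | excess | none
    diagnostics: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.share_pct <= 100.0):
            raise ValidationError("share_pct must lie in [0, 100]")
        for w in (self.w_p, self.w_o):
            if not (-1e-9 <= w <= 1 + 1e-9):
                raise ValidationError("retained fractions must lie in [0, 1]")


def theoretical_affected(
    eps_p: Spectrum, N_p: float, eps_o: Spectrum, N_o: float, x: float
) -> tuple[Spectrum, float]:
    """Non-interacting-reference spectrum and affected number at mole fraction x."""
    if not (0.0 <= x <= 1.0):
        raise DomainError(f"x must be in [0, 1], got {x}")
    if N_p <= 0 or N_o <= 0:
        raise DomainError("affected numbers must be positive")
    if eps_p.grid.shape != eps_o.grid.shape or not np.allclose(eps_p.grid, eps_o.grid, atol=1e-9, rtol=0):
        raise ValidationError("component spectra must share the common grid")
    n_theor = (1 - x) * N_p + x * N_o
    values = ((1 - x) * N_p * eps_p.values + x * N_o * eps_o.values) / n_theor
    return Spectrum(eps_p.grid, values, role="theoretical", meta={"x": x}), float(n_theor)


def delta_N(N_exp: float, N_theor: float, eps_tol: float = 0.0) -> tuple[float, str]:
    """Affected-water surplus/deficit and its interpretation.

    Negative delta_N beyond the tolerance means shared water (hydration
    spheres overlap); positive means excess water (additional molecules are
    perturbed only in the mixture).
    """
    if N_exp <= 0 or N_theor <= 0:
        raise DomainError("affected numbers must be positive")
    dn = N_exp - N_theor
    if dn < -eps_tol:
        label = "shared"
    elif dn > eps_tol:
        label = "excess"
    else:
        label = "none"
    return float(dn), label


def _lex_linprog(A_ub, b_ub, objectives, bounds):
    """Lexicographic LP: optimise objectives in order, freezing each level.

    Each objective is a (c, sense) pair with sense +1 for maximise and -1 for
    minimise.  Each solved level is frozen with a small slack before moving
    to the next; because the solver's reported optimum can overstate the
    exactly-achievable value by its feasibility tolerance, the slack is
    grown geometrically until the whole cascade is feasible.
    """
    A_ub = np.asarray(A_ub, dtype=float)
    b_ub = np.asarray(b_ub, dtype=float)
    last_msg = ""
    for slack_scale in (1e-8, 1e-7, 1e-6, 1e-5, 1e-4):
        extra_A, extra_b = [], []
        x = None
        ok = True
        for c, sense in objectives:
            c = np.asarray(c, dtype=float)
            A = A_ub if not extra_A else np.vstack([A_ub, np.array(extra_A)])
            b = b_ub if not extra_b else np.concatenate([b_ub, np.array(extra_b)])
            res = linprog(-sense * c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
            if not res.success:
                ok = False
                last_msg = res.message
                break
            x = res.x
            opt = float(c @ x)
            slack = slack_scale * max(1.0, abs(opt))
            # freeze: sense*c@x >= sense*opt - slack
            extra_A.append(-sense * c)
            extra_b.append(-sense * opt + slack)
        if ok:
            return x
    raise ValidationError(f"decomposition LP failed: {last_msg}")


def decompose_shared_excess(t: TernaryInputs, delta=0.0, eps_tol: float | None = None) -> TernaryDecomposition:
    """Split the mixture's affected water into pure-solute and shared/excess parts.

    Maximises the retained pure-solute affected water subject to the
    remainder staying above -delta everywhere.  Degenerate optima are broken
    by maximising w_p + w_o and then preferring w_p = w_o.  ``delta`` is a
    non-negativity tolerance on the intensity scale of N*eps (use ~3x the
    noise level of N_exp*eps_exp); it may be a scalar or a pointwise array.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise DomainError("delta must be >= 0")
    grid = t.eps_exp.grid
    target = t.N_exp * t.eps_exp.values
    if np.min(target + delta) < 0:
        raise ValidationError(
            "experimental affected spectrum has negative dips beyond delta; "
            "decomposition is infeasible even at w_p = w_o = 0"
        )
    a = (1 - t.x) * t.N_p  # water retained per unit w_p
    b = t.x * t.N_o
    comp_p = a * t.eps_p.values
    comp_o = b * t.eps_o.values
    # variables (w_p, w_o, s) with s an epigraph bound on |w_p - w_o|;
    # lexicographic: retained water, then w_p + w_o, then minimal s
    n_con = len(np.broadcast_to(target, target.shape))
    A_ub = np.vstack(
        [
            np.column_stack([comp_p, comp_o, np.zeros(n_con)]),
            [1.0, -1.0, -1.0],  # w_p - w_o <= s
            [-1.0, 1.0, -1.0],  # w_o - w_p <= s
        ]
    )
    b_ub = np.concatenate([np.broadcast_to(target + delta, (n_con,)), [0.0, 0.0]])
    bounds = [(0.0, 1.0), (0.0, 1.0), (0.0, None)]
    w = _lex_linprog(
        A_ub,
        b_ub,
        [
            (np.array([a, b, 0.0]), +1),
            (np.array([1.0, 1.0, 0.0]), +1),
            (np.array([0.0, 0.0, 1.0]), -1),
        ],
        bounds,
    )
    w_p, w_o = float(np.clip(w[0], 0, 1)), float(np.clip(w[1], 0, 1))

    eps_theor, n_theor = theoretical_affected(t.eps_p, t.N_p, t.eps_o, t.N_o, t.x)
    if eps_tol is None:
        eps_tol = float(np.hypot(t.sigma_N_exp, t.sigma_N_theor))
    dn, label = delta_N(t.N_exp, n_theor, eps_tol=eps_tol)

    r = target - w_p * comp_p - w_o * comp_o
    n_sh = t.N_exp - w_p * a - w_o * b
    total_intensity = float(np.trapezoid(target, grid))
    share = 100.0 * float(np.trapezoid(r, grid)) / total_intensity if total_intensity > 0 else 0.0
    share = float(np.clip(share, 0.0, 100.0))
    if n_sh > 1e-9:
        eps_sh_values = r / n_sh
    else:
        n_sh = max(n_sh, 0.0)
        eps_sh_values = np.zeros_like(r)
    eps_sh = Spectrum(grid, eps_sh_values, role="shared_excess", meta={"N_sh": n_sh})
    return TernaryDecomposition(
        eps_theor=eps_theor,
        N_theor=n_theor,
        delta_N=dn,
        w_p=w_p,
        w_o=w_o,
        eps_sh=eps_sh,
        N_sh=float(n_sh),
        share_pct=share,
        label=label,
        diagnostics={
            "delta": float(np.max(delta)),
            "eps_tol": eps_tol,
            "min_remainder": float(np.min(r)),
            "retained_water": w_p * a + w_o * b,
        },
    )


def denoised_decomposition(
    t: TernaryInputs,
    k: float = 3.0,
    width: float = 25.0,
    noise_sigma: np.ndarray | None = None,
    eps_tol: float | None = None,
) -> TernaryDecomposition:
    """Shared/excess decomposition on consistently denoised spectra.

    The pointwise noise level of the experimental spectrum is estimated by
    polynomial detrending (or supplied), all three spectra are smoothed with
    the same quadratic Savitzky-Golay filter (a linear operation, so the
    mixture weights are unchanged), and the non-negativity tolerance is set
    to k times the *smoothed* noise on the N*eps intensity scale.  This is
    the recommended entry point for measured (noisy) affected spectra; for
    exact synthetic inputs call :func:`decompose_shared_excess` directly.
    """
    from .affected import _pointwise_noise_variance
    from .spectra import denoise, savgol_noise_gain

    grid = t.eps_exp.grid
    spacing = float(np.median(np.diff(grid)))
    if noise_sigma is None:
        noise_sigma = np.sqrt(_pointwise_noise_variance(t.eps_exp.values, grid))
    g = savgol_noise_gain(width, spacing)
    smooth = lambda s: denoise(s, width=width)
    t_s = TernaryInputs(
        eps_p=smooth(t.eps_p),
        N_p=t.N_p,
        eps_o=smooth(t.eps_o),
        N_o=t.N_o,
        x=t.x,
        eps_exp=smooth(t.eps_exp),
        N_exp=t.N_exp,
        sigma_N_exp=t.sigma_N_exp,
        sigma_N_theor=t.sigma_N_theor,
    )
    delta = k * g * np.asarray(noise_sigma) * t.N_exp
    return decompose_shared_excess(t_s, delta=delta, eps_tol=eps_tol)
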
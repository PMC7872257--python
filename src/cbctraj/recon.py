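"""ASD-POCS iterative reconstruction for arbitrary multi-arc trajectories.

Each outer iteration alternates two stages:

1. a data-consistency pass — ordered-subsets SART using the matched
   projector/backprojector pair, with an optional nonnegativity clamp
   (projection onto the convex sets "data tubes" and the positive orthant);
2. adaptive steepest-descent minimization of the isotropic total variation,
   whose step length is tied to the magnitude of the first data update and
   shrunk whenever the TV stage moves the image more than a set fraction of
   the data stage (the classic adaptive schedule of Sidky & Pan).

The combination regularizes the severely underdetermined limited-angle /
sparse-view systems produced by short-arc trajectories.  Initialization is
the zero volume and the projection ordering is the trajectory's own angle
order, so reconstructions are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryParams
from .projector import (
    GridSpec,
    ProjectionStack,
    Volume,
    _RaySampler,
    forward_project,
)

_EPS_TV = 1e-8


@dataclass(frozen=True)
class ReconParams:
    """ASD-POCS hyperparameters.

    ``n_outer_iterations`` is deliberately small (default 5): with matched
    SART updates the VOI contrast needed by the trajectory objective is
    established in the first few sweeps.  The remaining knobs follow the
    standard adaptive schedule: ``tv_step_ratio`` scales the first TV step
    to the first data-update magnitude, ``tv_reduction`` shrinks the TV step
    when it dominates (``max_tv_data_ratio``), ``relaxation_reduction``
    anneals the SART relaxation.
    """

    n_outer_iterations: int = 5
    sart_relaxation: float = 1.0
    tv_descent_steps: int = 20
    tv_step_ratio: float = 0.2
    max_tv_data_ratio: float = 0.95
    tv_reduction: float = 0.95
    relaxation_reduction: float = 0.995
    nonnegativity: bool = True
    subset_size: int = 10
    step_voxels: float = 0.5

    def __post_init__(self) -> None:
        if self.n_outer_iterations < 1:
            raise ValueError("need at least one outer iteration")
        if not (0 <= self.sart_relaxation < 2):
            raise ValueError("SART relaxation must be in [0, 2)")
        if self.tv_descent_steps < 0:
            raise ValueError("tv_descent_steps must be >= 0")
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")


def total_variation(voxels: np.ndarray) -> float:
    """Isotropic TV: sum over voxels of the forward-difference gradient norm."""
    sq = np.zeros_like(voxels)
    for ax in range(3):
        d = np.diff(voxels, axis=ax)
        pad = [(0, 0)] * 3
        pad[ax] = (0, 1)
        sq = sq + np.pad(d, pad) ** 2
    return float(np.sqrt(sq + _EPS_TV).sum())


def _tv_gradient(x: np.ndarray) -> np.ndarray:
    """Gradient of the smoothed isotropic TV functional.

    With forward differences ``D_a x[v] = x[v+e_a] − x[v]`` and
    ``N = sqrt(Σ_a (D_a x)² + ε)``, the derivative at voxel ``w`` is
    ``Σ_a (D_a x[w−e_a]/N[w−e_a] − D_a x[w]/N[w])``.
    """
    grads = []
    for ax in range(3):
        d = np.diff(x, axis=ax)
        pad = [(0, 0)] * 3
        pad[ax] = (0, 1)
        grads.append(np.pad(d, pad))
    norm = np.sqrt(sum(g * g for g in grads) + _EPS_TV)
    out = np.zeros_like(x)
    crop = tuple(slice(0, s) for s in x.shape)
    for ax in range(3):
        gn = grads[ax] / norm
        out -= gn
        pad = [(0, 0)] * 3
        pad[ax] = (1, 0)
        out += np.pad(gn, pad)[crop]
    return out


def tv_descent(volume: Volume, steps: int, step_size: float,
               max_backtracks: int = 5) -> Volume:
    """Steepest descent on TV with normalized gradient and backtracking.

    Each step moves by ``step_size`` along the negative normalized TV
    gradient; a step that would raise the TV is halved (up to
    ``max_backtracks`` times) before the descent gives up, so the TV of the
    output never exceeds the TV of the input regardless of how the outer
    schedule scales the step.
    """
    if steps == 0 or step_size == 0.0:
        return volume.like(volume.voxels.copy())
    x = volume.voxels.copy()
    tv = total_variation(x)
    for _ in range(steps):
        g = _tv_gradient(x)
        gnorm = float(np.linalg.norm(g))
        if gnorm == 0.0:
            break
        step = step_size
        for _attempt in range(max_backtracks + 1):
            candidate = x - step * g / gnorm
            tv_new = total_variation(candidate)
            if tv_new <= tv:
                break
            step *= 0.5
        else:
            break  # could not find a non-increasing step
        x, tv = candidate, tv_new
    return volume.like(x)


class SartSystem:
    """Projection system for one trajectory: ray samplers, SART weights.

    Caches the per-pose ray-sample geometry (shared by the forward and
    adjoint operators) and the SART normalization constants — ray sums of a
    unit volume per projection, backprojected ray densities per subset — so
    repeated sweeps over the same trajectory pay the geometric setup once.
    Sampler caching degrades gracefully to on-demand rebuilding when the
    geometry would exceed ``cache_budget_bytes``.
    """

    def __init__(
        self,
        stack: ProjectionStack,
        grid: GridSpec,
        geom: GeometryParams,
        subset_size: int = 10,
        step_voxels: float = 0.5,
        cache_budget_bytes: int = 1_200_000_000,
    ) -> None:
        if len(stack) == 0:
            raise ValueError("empty projection stack")
        for im in stack.images:
            if not np.all(np.isfinite(im)):
                raise ValueError("projections contain non-finite values")
        self.stack = stack
        self.grid = grid
        self.geom = geom
        self.step_voxels = step_voxels
        n = len(stack)
        self.subsets = [
            list(range(s0, min(s0 + subset_size, n))) for s0 in range(0, n, subset_size)
        ]
        self._samplers: dict[int, _RaySampler] = {}
        self._cache_bytes = 0
        self._budget = cache_budget_bytes
        ones = np.ones(grid.shape)
        self.row_sums = [self._sampler(i).project(ones) for i in range(n)]
        self.col_sums = []
        for idx in self.subsets:
            col = np.zeros(grid.shape)
            for i in idx:
                self._sampler(i).backproject(np.ones_like(stack.images[i]), col)
            self.col_sums.append(col)

    def _sampler(self, i: int) -> _RaySampler:
        if i in self._samplers:
            return self._samplers[i]
        s = _RaySampler(self.grid, self.stack.poses[i], self.geom, self.step_voxels)
        if self._cache_bytes + s.nbytes <= self._budget:
            self._samplers[i] = s
            self._cache_bytes += s.nbytes
        return s

    def project_one(self, voxels: np.ndarray, i: int) -> np.ndarray:
        return self._sampler(i).project(voxels)

    def residual_norm(self, voxels: np.ndarray) -> float:
        sq = 0.0
        for i, b in enumerate(self.stack.images):
            sq += float(np.sum((self.project_one(voxels, i) - b) ** 2))
        return float(np.sqrt(sq))

    def sart_sweep(
        self, voxels: np.ndarray, relaxation: float, nonnegativity: bool
    ) -> np.ndarray:
        """One ordered-subsets SART sweep (subsets in trajectory order)."""
        x = voxels.copy()
        if relaxation == 0.0:
            return x
        for subset_idx, idx in enumerate(self.subsets):
            upd = np.zeros(self.grid.shape)
            for i in idx:
                sim = self.project_one(x, i)
                rs = self.row_sums[i]
                resid = np.where(
                    rs > 1e-9, (self.stack.images[i] - sim) / np.maximum(rs, 1e-9), 0.0
                )
                self._sampler(i).backproject(resid, upd)
            col = self.col_sums[subset_idx]
            x = x + relaxation * np.where(col > 1e-9, upd / np.maximum(col, 1e-9), 0.0)
            if nonnegativity:
                np.clip(x, 0.0, None, out=x)
        return x


def sart_pass(
    volume: Volume,
    stack: ProjectionStack,
    params: GeometryParams,
    relaxation: float = 1.0,
    subset_size: int = 10,
    nonnegativity: bool = True,
    step_voxels: float = 0.5,
    system: SartSystem | None = None,
) -> Volume:
    """One ordered-subsets SART sweep over all projections.

    Updates use the standard SART normalization (ray sums on the projection
    side, backprojected ray densities on the volume side).  ``relaxation``
    of 0 returns the input unchanged.
    """
    system = system or SartSystem(
        stack, GridSpec.of(volume), params, subset_size, step_voxels
    )
    return volume.like(system.sart_sweep(volume.voxels, relaxation, nonnegativity))


def data_residual_norm(
    volume: Volume, stack: ProjectionStack, params: GeometryParams,
    step_voxels: float = 0.5,
) -> float:
    """Euclidean norm of the projection-domain residual ``‖Ax − b‖``."""
    sim = forward_project(volume, stack.poses, params, step_voxels)
    return float(
        np.sqrt(sum(np.sum((a - b) ** 2) for a, b in zip(sim.images, stack.images)))
    )


def asd_pocs(
    stack: ProjectionStack,
    grid: GridSpec,
    geom: GeometryParams,
    params: ReconParams | None = None,
    history: list | None = None,
    callback=None,
) -> Volume:
    """ASD-POCS reconstruction of a projection stack onto ``grid``.

    Parameters
    ----------
    history
        Optional list; one dict per outer iteration is appended with the
        data residual, the TV before/after the descent stage and the step
        sizes in effect.
    callback
        Optional ``callback(iteration, volume)`` invoked after each outer
        iteration (e.g. to track error against a known ground truth).
    """
    params = params or ReconParams()
    system = SartSystem(
        stack, grid, geom, params.subset_size, params.step_voxels
    )
    x = grid.zeros()
    beta = params.sart_relaxation
    dtvg = 0.0
    for it in range(params.n_outer_iterations):
        x_prev = x.voxels.copy()
        x = x.like(system.sart_sweep(x.voxels, beta, params.nonnegativity))
        dg = float(np.linalg.norm(x.voxels - x_prev))
        resid_after_sart = (
            system.residual_norm(x.voxels) if history is not None else None
        )
        if it == 0:
            dtvg = params.tv_step_ratio * dg
        tv_before = total_variation(x.voxels)
        x_tv = tv_descent(x, params.tv_descent_steps, dtvg)
        if params.nonnegativity:
            # clipping is 1-Lipschitz per voxel pair, so TV cannot increase
            np.clip(x_tv.voxels, 0.0, None, out=x_tv.voxels)
        dp = float(np.linalg.norm(x_tv.voxels - x.voxels))
        tv_after = total_variation(x_tv.voxels)
        if dp > params.max_tv_data_ratio * dg and it > 0:
            dtvg *= params.tv_reduction
        x = x_tv
        if history is not None:
            history.append(
                {
                    "iteration": it,
                    "residual": system.residual_norm(x.voxels),
                    "residual_after_sart": resid_after_sart,
                    "tv_before_descent": tv_before,
                    "tv_after_descent": tv_after,
                    "data_update_norm": dg,
                    "tv_update_norm": dp,
                    "relaxation": beta,
                    "tv_step": dtvg,
                }
            )
        if callback is not None:
            callback(it, x)
        beta *= params.relaxation_reduction
    return x
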
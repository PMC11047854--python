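"""Nested Cartesian grid tiers with 2x refinement and two-way coupling.

The domain is covered by a coarse outer tier; each finer tier is a nested box
whose spacing is half its parent's.  Acoustic scaling (dt proportional to dx,
lattice speed c = dx/dt identical on every tier) keeps lattice velocities
tier-invariant, and the relaxation time per tier is set from the constant
physical viscosity: ``tau_fine - 1/2 = 2 (tau_coarse - 1/2)``.

Coupling per coarse step: the parent steps once; the child runs two sub-steps,
its ghost rim filled from the parent by trilinear interpolation in space and
linear interpolation in time, with the non-equilibrium part rescaled by the
``tau * dt`` ratio (Dupuis-Chopard); finally parent nodes coincident with the
child interior are overwritten by the restricted child state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .lattice import D3Q27, equilibrium
from .solver import FluidBlock

__all__ = ["TierSpec", "BlockLayout", "build_layout", "MultiblockSolver"]


@dataclass(frozen=True)
class TierSpec:
    """One tier's geometry: interior node counts, spacing, lab origin."""

    shape: tuple
    dx: float
    origin: tuple

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * self.dx


@dataclass(frozen=True)
class BlockLayout:
    """Coarsest-to-finest tier stack; adjacent spacings differ by exactly 2x."""

    tiers: tuple

    def __post_init__(self):
        for parent, child in zip(self.tiers, self.tiers[1:]):
            if not np.isclose(parent.dx / child.dx, 2.0):
                raise ValueError("adjacent tier spacing ratio must be 2")
            off = (np.asarray(child.origin) - np.asarray(parent.origin)) / parent.dx
            if not np.allclose(off, np.round(off), atol=1e-9):
                raise ValueError("child origin must lie on the parent grid")
            if np.any(np.asarray(child.origin) < np.asarray(parent.origin) - 1e-9) or np.any(
                child.extent > parent.extent + 1e-9
            ):
                raise ValueError("tiers must be strictly nested")

    @property
    def finest(self) -> TierSpec:
        return self.tiers[-1]


def build_layout(
    chord: float,
    resolution: int,
    domain_chords: float = 40.0,
    n_tiers: int = 4,
    sweep_radius_chords: float | None = None,
) -> BlockLayout:
    """Tiered layout: cubic domain of ``domain_chords`` L per side, finest
    spacing ``L / resolution``, each outer tier twice as coarse.

    The finest tier is sized to contain the full wing sweep (default radius:
    wing length + half chord, in chords, plus margin) centred on the hinge at
    the domain centre; every tier boundary stays at least two of its parent's
    cells away from the next tier.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    L = chord
    if sweep_radius_chords is None:
        sweep_radius_chords = 2.39 / 0.78 + 0.5  # wing span + half chord, in L
    dxs = [L / resolution * 2 ** (n_tiers - 1 - lev) for lev in range(n_tiers)]
    half_domain = 0.5 * domain_chords * L
    tiers = []
    # half-widths: finest covers the sweep + 2 coarse cells; each parent 2x wider
    half_fine = sweep_radius_chords * L + 2 * dxs[0]
    prev_half = None
    for lev in range(n_tiers):
        dx = dxs[lev]
        if lev == 0:
            half = half_domain
        else:
            # stay at least two parent cells inside the parent tier
            half = min(
                half_fine * 2 ** (n_tiers - 1 - lev),
                prev_half - 2 * dxs[lev - 1],
            )
        # snap to the parent grid
        parent_dx = dxs[lev - 1] if lev > 0 else dx
        n_half = int(np.ceil(half / parent_dx)) * int(round(parent_dx / dx))
        shape = (2 * n_half + 1,) * 3
        origin = (-n_half * dx,) * 3
        tiers.append(TierSpec(shape=shape, dx=dx, origin=origin))
        prev_half = n_half * dx
    if tiers[-1].extent[0] < sweep_radius_chords * L:
        raise ValueError("wing sweep is not contained in the finest tier")
    return BlockLayout(tiers=tuple(tiers))


def _rim_indices(block: FluidBlock) -> np.ndarray:
    """Padded indices of the ghost rim of a non-periodic block, (N, 3)."""
    full = np.array(block.f.shape[:3])
    idx = np.indices(full).reshape(3, -1).T
    on_rim = np.zeros(len(idx), dtype=bool)
    for ax in range(3):
        if not block.periodic[ax]:
            on_rim |= (idx[:, ax] == 0) | (idx[:, ax] == full[ax] - 1)
    return idx[on_rim]


class MultiblockSolver:
    """Recursive stepping of a coarse-to-fine stack of :class:`FluidBlock`.

    ``step()`` advances the whole hierarchy by one coarsest-tier time step.
    An optional ``boundary_hook(finest_block)`` is called on the finest tier
    at each of its sub-steps (used to apply the immersed plates there).
    """

    def __init__(self, blocks, boundary_hook=None):
        self.blocks = list(blocks)
        self.boundary_hook = boundary_hook
        self.lattice = D3Q27
        for parent, child in zip(self.blocks, self.blocks[1:]):
            ratio = parent.dx / child.dx
            if not np.isclose(ratio, 2.0):
                raise ValueError("adjacent blocks must refine by exactly 2")

    # -- inter-tier transfer ------------------------------------------------

    def _neq_factor(self, parent: FluidBlock, child: FluidBlock) -> float:
        """pneq multiplier for parent -> child transfer: (tau dt)_c / (tau dt)_p."""
        return (child.tau * child.dt) / (parent.tau * parent.dt)

    def _sample_parent(self, parent: FluidBlock, sites_lab: np.ndarray):
        """(p, u, pneq27) of the parent, trilinearly sampled at lab points."""
        parent._update_macro()
        g = ((sites_lab - parent.origin) / parent.dx + np.asarray(parent.pad)).T
        p = map_coordinates(parent._p, g, order=1, mode="nearest")
        u = np.stack(
            [
                map_coordinates(arr, g, order=1, mode="nearest")
                for arr in (parent._ux, parent._uy, parent._uz)
            ],
            axis=-1,
        )
        # non-equilibrium part on the parent sub-box covering the sites
        lo = np.maximum(np.floor(g.min(axis=1)).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(g.max(axis=1)).astype(int) + 2, parent.f.shape[:3])
        sub = tuple(slice(a, b) for a, b in zip(lo, hi))
        usub = np.stack([parent._ux[sub], parent._uy[sub], parent._uz[sub]], axis=-1)
        pneq_sub = parent.f[sub] - equilibrium(parent._p[sub], usub, self.lattice)
        gs = g - lo[:, None]
        pneq = np.stack(
            [
                map_coordinates(pneq_sub[..., a], gs, order=1, mode="nearest")
                for a in range(27)
            ],
            axis=-1,
        )
        return p, u, pneq

    def _fill_child_ghosts(self, child: FluidBlock, rim, sample0, sample1, theta):
        p = (1 - theta) * sample0[0] + theta * sample1[0]
        u = (1 - theta) * sample0[1] + theta * sample1[1]
        pneq = (1 - theta) * sample0[2] + theta * sample1[2]
        vals = equilibrium(p, u, self.lattice) + pneq
        child.f[rim[:, 0], rim[:, 1], rim[:, 2]] = vals

    def _restrict(self, parent: FluidBlock, child: FluidBlock, margin: int = 2):
        """Overwrite parent nodes coincident with the child interior."""
        child._update_macro()
        shift = (np.asarray(child.origin) - np.asarray(parent.origin)) / parent.dx
        pshift = np.round(shift).astype(int)
        sl_c = []
        sl_p = []
        for ax in range(3):
            n_int = child.shape[ax]
            c0 = child.pad[ax] + margin
            c1 = child.pad[ax] + n_int - margin
            # child interior indices coincident with parent nodes: every 2nd
            first = c0 + ((child.pad[ax] - c0) % 2)
            sl_c.append(slice(first, c1, 2))
            p_first = parent.pad[ax] + pshift[ax] + (first - child.pad[ax]) // 2
            count = len(range(first, c1, 2))
            sl_p.append(slice(p_first, p_first + count))
        sl_c, sl_p = tuple(sl_c), tuple(sl_p)
        pc = child._p[sl_c]
        uc = np.stack(
            [child._ux[sl_c], child._uy[sl_c], child._uz[sl_c]], axis=-1
        )
        peq = equilibrium(pc, uc, self.lattice)
        pneq = child.f[sl_c] - peq
        parent.f[sl_p] = peq + pneq / self._neq_factor(parent, child)

    # -- stepping -----------------------------------------------------------

    def _advance(self, level: int):
        block = self.blocks[level]
        has_child = level + 1 < len(self.blocks)
        if has_child:
            child = self.blocks[level + 1]
            rim = self._rims[level + 1]
            sites = rim * child.dx + (
                np.asarray(child.origin) - np.asarray(child.pad) * child.dx
            )
            pre = self._sample_parent(block, sites)
        if level == 0:
            block.step()
        else:
            # ghost rim was filled from the parent; do not overwrite it
            if self.boundary_hook is not None and level == len(self.blocks) - 1:
                self.boundary_hook(block)
            else:
                block.collide_stream()
            block.commit()
        if has_child:
            post = self._sample_parent(block, sites)
            kappa = self._neq_factor(block, child)
            pre = (pre[0], pre[1], pre[2] * kappa)
            post = (post[0], post[1], post[2] * kappa)
            for sub in range(2):
                self._fill_child_ghosts(child, rim, pre, post, sub / 2.0)
                self._advance(level + 1)
            self._restrict(block, child)

    def step(self):
        """Advance the hierarchy by one coarsest-tier step."""
        if not hasattr(self, "_rims"):
            self._rims = {
                lev: _rim_indices(b) for lev, b in enumerate(self.blocks) if lev > 0
            }
        self._advance(0)
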
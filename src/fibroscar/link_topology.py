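"""Tissue geometry and the random non-local myocyte-fibroblast link sets.

A link set attaches ``n_units`` fibroblast units to the lattice: each
unit gets one uniformly random *proximal* grid point inside the scar,
plus a Poisson(lambda) number of candidate *distal* attachments, each
drawn uniformly from a candidate pool and accepted only if it lies
within a Euclidean distance ``Lmax`` (mm) of the unit's proximal point.
Rejected candidates are discarded (not redrawn) and duplicate hits on an
already-attached point are skipped, so with Lmax large the accepted
distal count is approximately Poisson(lambda * p_acc) with p_acc the
pool fraction within Lmax.  With the default whole-lattice pool, units
whose proximal point sits near the scar rim acquire attachments in the
surrounding normal tissue — the border-zone bridge this model studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["TissueGeometry", "LinkSet", "generate_links", "degree_histogram",
           "invert_links", "links_from_inverse", "InverseLinks",
           "REALISATION_SEEDS", "D_REG_DEFAULT", "DX_MM_DEFAULT"]

D_REG_DEFAULT = 0.001   # cm^2/ms, normal-tissue diffusion
DX_MM_DEFAULT = 0.25    # mm, lattice spacing

#: fixed seeds for the five documented spatial realisations ("case 1..5")
REALISATION_SEEDS = {1: 7101, 2: 7102, 3: 7103, 4: 7104, 5: 7105}


@dataclass
class TissueGeometry:
    """Square-lattice tissue with an optional diffusively uncoupled scar.

    ``scar_mask`` marks grid points with zero diffusion; everywhere else
    the diffusion constant is ``d_reg`` (cm^2/ms).  The border-zone
    annulus and the radial sampling line are derived properties.
    """

    n_rows: int
    n_cols: int
    scar_mask: np.ndarray
    dx_mm: float = DX_MM_DEFAULT
    d_reg: float = D_REG_DEFAULT
    shape_spec: str = "custom"

    def __post_init__(self):
        self.scar_mask = np.asarray(self.scar_mask, dtype=bool)
        if self.scar_mask.shape != (self.n_rows, self.n_cols):
            raise ValueError("scar mask shape does not match lattice")
        if self.dx_mm <= 0 or self.d_reg < 0:
            raise ValueError("dx must be > 0 and d_reg >= 0")

    # -- constructors -------------------------------------------------------
    @classmethod
    def uniform(cls, n_rows: int, n_cols: int, dx_mm: float = DX_MM_DEFAULT,
                d_reg: float = D_REG_DEFAULT) -> "TissueGeometry":
        return cls(n_rows, n_cols, np.zeros((n_rows, n_cols), dtype=bool),
                   dx_mm, d_reg, shape_spec="uniform")

    @classmethod
    def circular_scar(cls, n: int, r_cm: float = 2.0,
                      dx_mm: float = DX_MM_DEFAULT,
                      d_reg: float = D_REG_DEFAULT) -> "TissueGeometry":
        """n x n domain with a centred circular scar of radius r_cm."""
        r_pts = r_cm * 10.0 / dx_mm
        ci = cj = n // 2
        ii, jj = np.mgrid[0:n, 0:n]
        mask = (ii - ci) ** 2 + (jj - cj) ** 2 <= r_pts ** 2
        return cls(n, n, mask, dx_mm, d_reg,
                   shape_spec=f"circle_R{r_cm}cm")

    @classmethod
    def line_scar(cls, n_rows: int = 60, n_cols: int = 200,
                  scar_width_pts: int = 1, dx_mm: float = DX_MM_DEFAULT,
                  d_reg: float = D_REG_DEFAULT) -> "TissueGeometry":
        """Strip with a full-height vertical scar band at mid-domain."""
        mask = np.zeros((n_rows, n_cols), dtype=bool)
        j0 = n_cols // 2 - scar_width_pts // 2
        mask[:, j0:j0 + scar_width_pts] = True
        return cls(n_rows, n_cols, mask, dx_mm, d_reg,
                   shape_spec=f"line_w{scar_width_pts}")

    # -- derived fields -----------------------------------------------------
    @property
    def scar_indices(self) -> np.ndarray:
        """(ns, 2) int array of scar grid points."""
        return np.argwhere(self.scar_mask)

    def diffusion_field(self) -> np.ndarray:
        d = np.full((self.n_rows, self.n_cols), self.d_reg)
        d[self.scar_mask] = 0.0
        return d

    def distance_to_scar_mm(self) -> np.ndarray:
        """Euclidean distance (mm) of each point to the nearest scar point."""
        if not self.scar_mask.any():
            return np.full((self.n_rows, self.n_cols), np.inf)
        return ndimage.distance_transform_edt(~self.scar_mask) * self.dx_mm

    def border_zone(self, links: "LinkSet | None" = None,
                    lmax_mm: float = 2.5) -> np.ndarray:
        """Non-scar points within Lmax of a scar point holding a link.

        Without a link set, falls back to distance from the whole rim.
        """
        if links is None:
            near = self.distance_to_scar_mm() <= lmax_mm
            return near & ~self.scar_mask
        anchor = np.zeros_like(self.scar_mask)
        for (i, j) in links.prox_ij:
            anchor[i, j] = True
        for u in range(links.n_units):
            for (i, j) in links.distal_of(u):
                if self.scar_mask[i, j]:
                    anchor[i, j] = True
        d = ndimage.distance_transform_edt(~anchor) * self.dx_mm
        return (d <= lmax_mm) & ~self.scar_mask

    def sampling_line(self) -> np.ndarray:
        """Ordered (s, 2) grid points of the radial sampling line.

        Runs along the centre row from the scar centre through the rim
        toward the pacing edge (column 0); index 0 is the innermost
        point.  Requires a scar.
        """
        if not self.scar_mask.any():
            raise ValueError("sampling line requires a scar")
        ii, jj = np.nonzero(self.scar_mask)
        ci = int(round(ii.mean()))
        cj = int(round(jj.mean()))
        return np.array([(ci, j) for j in range(cj, -1, -1)])

    def to_dict(self) -> dict:
        return {"n_rows": self.n_rows, "n_cols": self.n_cols,
                "dx_mm": self.dx_mm, "d_reg": self.d_reg,
                "shape_spec": self.shape_spec}


# ---------------------------------------------------------------------------
@dataclass
class LinkSet:
    """Bipartite fibroblast-unit to grid-point attachments (CSR-like).

    ``prox_ij[u]`` is unit u's proximal scar point; its distal points
    are ``distal_ij[distal_ptr[u]:distal_ptr[u+1]]``.  All links share
    one conductance ``gs_nS`` (G_loc = G_long).
    """

    prox_ij: np.ndarray                 # (n_units, 2) int
    distal_ptr: np.ndarray              # (n_units + 1,) int
    distal_ij: np.ndarray               # (n_distal, 2) int
    gs_nS: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.prox_ij = np.asarray(self.prox_ij, dtype=np.int64)
        self.distal_ptr = np.asarray(self.distal_ptr, dtype=np.int64)
        self.distal_ij = np.asarray(self.distal_ij, dtype=np.int64).reshape(-1, 2)
        if self.distal_ptr.size != self.n_units + 1:
            raise ValueError("distal_ptr must have n_units + 1 entries")
        if self.gs_nS < 0:
            raise ValueError("Gs must be >= 0")

    @property
    def n_units(self) -> int:
        return self.prox_ij.shape[0]

    def distal_of(self, u: int) -> np.ndarray:
        return self.distal_ij[self.distal_ptr[u]:self.distal_ptr[u + 1]]

    def degrees(self) -> np.ndarray:
        """Attachment count per unit (proximal + distal)."""
        return 1 + np.diff(self.distal_ptr)

    def with_gs(self, gs_nS: float) -> "LinkSet":
        return LinkSet(self.prox_ij, self.distal_ptr, self.distal_ij,
                       gs_nS=gs_nS, meta=dict(self.meta))

    def flat_links(self, n_cols: int):
        """Per-link arrays (point_i, point_j, unit, gs) incl. proximal links."""
        deg = self.degrees()
        total = int(deg.sum())
        li = np.empty(total, dtype=np.int64)
        lj = np.empty(total, dtype=np.int64)
        lu = np.empty(total, dtype=np.int64)
        pos = 0
        for u in range(self.n_units):
            li[pos] = self.prox_ij[u, 0]
            lj[pos] = self.prox_ij[u, 1]
            lu[pos] = u
            pos += 1
            d = self.distal_of(u)
            k = d.shape[0]
            li[pos:pos + k] = d[:, 0]
            lj[pos:pos + k] = d[:, 1]
            lu[pos:pos + k] = u
            pos += k
        lg = np.full(total, self.gs_nS)
        return li, lj, lu, lg

    def validate(self, geom: TissueGeometry, lmax_mm: float | None = None):
        """Assert the generation constraints for every unit."""
        lmax = self.meta.get("lmax_mm") if lmax_mm is None else lmax_mm
        for u in range(self.n_units):
            pi, pj = self.prox_ij[u]
            if not geom.scar_mask[pi, pj]:
                raise ValueError(f"unit {u}: proximal point not in scar")
            d = self.distal_of(u)
            pts = {(pi, pj)}
            for (i, j) in d:
                r = math.hypot(i - pi, j - pj) * geom.dx_mm
                if lmax is not None and r > lmax + 1e-9:
                    raise ValueError(
                        f"unit {u}: distal point at {r:.3f} mm > Lmax")
                if (i, j) in pts:
                    raise ValueError(f"unit {u}: duplicate attachment")
                pts.add((i, j))


def generate_links(geom: TissueGeometry, n_units: int, lam: float,
                   lmax_mm: float, seed: int, gs_nS: float = 1.0,
                   candidate_pool: str = "lattice") -> LinkSet:
    """Draw a random link set (reproducible for a given seed).

    candidate_pool : "lattice" draws distal candidates uniformly from
        all grid points (links may bridge from the scar into the
        surrounding tissue — the default border-zone mechanism);
        "scar" restricts candidates to scar points.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lmax_mm < 0:
        raise ValueError("Lmax must be >= 0")
    scar_idx = geom.scar_indices
    if scar_idx.shape[0] == 0:
        raise ValueError("cannot place fibroblast units on an empty scar")
    if candidate_pool == "lattice":
        pool = np.argwhere(np.ones_like(geom.scar_mask))
    elif candidate_pool == "scar":
        pool = scar_idx
    else:
        raise ValueError(f"unknown candidate pool {candidate_pool!r}")

    rng = np.random.default_rng(seed)
    prox = scar_idx[rng.integers(0, scar_idx.shape[0], size=n_units)]
    kdraw = rng.poisson(lam, size=n_units)
    cand = pool[rng.integers(0, pool.shape[0], size=int(kdraw.sum()))]

    lmax_pts2 = (lmax_mm / geom.dx_mm) ** 2
    ptr = np.zeros(n_units + 1, dtype=np.int64)
    distal = []
    pos = 0
    for u in range(n_units):
        k = kdraw[u]
        pi, pj = prox[u]
        seen = {(int(pi), int(pj))}
        for c in range(pos, pos + k):
            ci, cj = int(cand[c, 0]), int(cand[c, 1])
            if (ci - pi) ** 2 + (cj - pj) ** 2 > lmax_pts2:
                continue
            if (ci, cj) in seen:
                continue
            seen.add((ci, cj))
            distal.append((ci, cj))
        pos += k
        ptr[u + 1] = len(distal)

    links = LinkSet(
        prox_ij=prox, distal_ptr=ptr,
        distal_ij=np.array(distal, dtype=np.int64).reshape(-1, 2),
        gs_nS=gs_nS,
        meta={"lambda": float(lam), "lmax_mm": float(lmax_mm),
              "n_units": int(n_units), "seed": int(seed),
              "candidate_pool": candidate_pool})
    links.validate(geom)
    return links


def degree_histogram(links: LinkSet) -> dict[int, float]:
    """Fraction of units per attachment count; fractions sum to 1."""
    if links.n_units == 0:
        raise ValueError("empty link set")
    deg = links.degrees()
    counts = np.bincount(deg)
    return {int(d): float(c) / links.n_units
            for d, c in enumerate(counts) if c > 0}


@dataclass
class InverseLinks:
    """Per-grid-point attachment lists.

    ``by_point[(i, j)]`` is a list of ``(unit, is_proximal, rank)``
    entries, where rank is the attachment's position in the unit's
    distal list (-1 for the proximal link) so the inversion is exactly
    reversible.
    """

    by_point: dict
    n_units: int
    gs_nS: float


def invert_links(links: LinkSet, geom: TissueGeometry) -> InverseLinks:
    by_point: dict = {}
    for u in range(links.n_units):
        pi, pj = (int(x) for x in links.prox_ij[u])
        by_point.setdefault((pi, pj), []).append((u, True, -1))
        for r, (i, j) in enumerate(links.distal_of(u)):
            by_point.setdefault((int(i), int(j)), []).append((u, False, r))
    return InverseLinks(by_point=by_point, n_units=links.n_units,
                        gs_nS=links.gs_nS)


def links_from_inverse(inv: InverseLinks) -> LinkSet:
    """Exact round-trip back to a LinkSet."""
    prox = np.zeros((inv.n_units, 2), dtype=np.int64)
    distal_per_unit: dict[int, list] = {u: [] for u in range(inv.n_units)}
    for (i, j), entries in inv.by_point.items():
        for (u, is_prox, rank) in entries:
            if is_prox:
                prox[u] = (i, j)
            else:
                distal_per_unit[u].append((rank, (i, j)))
    ptr = np.zeros(inv.n_units + 1, dtype=np.int64)
    distal = []
    for u in range(inv.n_units):
        for _, pt in sorted(distal_per_unit[u]):
            distal.append(pt)
        ptr[u + 1] = len(distal)
    return LinkSet(prox_ij=prox, distal_ptr=ptr,
                   distal_ij=np.array(distal, dtype=np.int64).reshape(-1, 2),
                   gs_nS=inv.gs_nS)
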
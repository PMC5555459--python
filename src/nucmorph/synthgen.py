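"""Synthetic data generation: microscopy-like nucleus images with exact ground
truth, and simulated recombinant-inbred-line (RIL) populations with planted
additive QTL.

Images emulate fields of spread, DAPI-stained interphase nuclei: bright
elliptical nuclei containing a handful of brighter, roughly circular
chromocenters on a dark, noisy background, rendered on an 8-bit scale.

Genotypes emulate a biparental RIL population obtained by repeated selfing:
every line is homozygous at every marker, coded ``A`` (recurrent/first parent
allele) or ``B`` (donor/second parent allele).  Along a chromosome the
genotype is a two-state Markov chain whose switch probability between markers
``d`` cM apart is the selfed-RIL recombination fraction

    R = 2r / (1 + 2r),   r = (1 - exp(-2 d / 100)) / 2   (Haldane),

i.e. the stationary behaviour of a RIL-by-selfing pedigree without simulating
the individual meioses.

Simulated traits have an explicit variance decomposition: a genetic line
value (sum of planted additive QTL effects, +a for the A allele, -a for B, at
the marker nearest each QTL), a between-line environmental component, and a
within-line per-nucleus component, so broad-sense heritability of the
generated data is known in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "haldane_r",
    "ril_recomb_fraction",
    "GeneticMap",
    "QTLSpecItem",
    "NucleusTruth",
    "make_genetic_map",
    "simulate_ril_genotypes",
    "simulate_trait_values",
    "render_nucleus_image",
    "random_nucleus_field",
]


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def haldane_r(d_cM):
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def ril_recomb_fraction(d_cM):
    """Observed switch probability between homozygous selfed-RIL genotypes.

    Applies the Haldane-Waddington transform R = 2r/(1+2r) to the Haldane
    recombination fraction r for a map distance ``d_cM``.
    """
    r = haldane_r(d_cM)
    return 2.0 * r / (1.0 + 2.0 * r)


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: one row per marker (marker, chrom, pos_cM).

    Positions within a chromosome are strictly increasing after exact
    duplicates are removed at construction; every chromosome carries at
    least two markers.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"marker", "chrom", "pos_cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if t.empty:
            raise ValueError("empty genetic map")
        t = t.drop_duplicates(subset=["chrom", "pos_cM"]).reset_index(drop=True)
        if t["marker"].duplicated().any():
            dups = t["marker"][t["marker"].duplicated()].tolist()
            raise ValueError(f"duplicate marker names: {dups}")
        for c, sub in t.groupby("chrom", sort=False):
            pos = sub["pos_cM"].to_numpy(dtype=float)
            if len(pos) < 2:
                raise ValueError(f"chromosome {c!r} has <2 markers")
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions on chromosome {c!r} not strictly increasing")
        object.__setattr__(self, "table", t)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def positions(self, chrom) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos_cM"].to_numpy(dtype=float)

    def chrom_markers(self, chrom) -> list[str]:
        return self.table.loc[self.table["chrom"] == chrom, "marker"].tolist()

    def span(self, chrom) -> tuple[float, float]:
        pos = self.positions(chrom)
        return float(pos[0]), float(pos[-1])

    def nearest_marker(self, chrom, pos_cM: float) -> str:
        pos = self.positions(chrom)
        if len(pos) == 0:
            raise ValueError(f"unknown chromosome {chrom!r}")
        i = int(np.argmin(np.abs(pos - pos_cM)))
        return self.chrom_markers(chrom)[i]

    def position_of(self, marker: str) -> tuple[object, float]:
        row = self.table.loc[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(marker)
        return row.iloc[0]["chrom"], float(row.iloc[0]["pos_cM"])


def make_genetic_map(n_chrom: int,
                     chrom_lengths_cM: Sequence[float],
                     marker_step_cM: float) -> GeneticMap:
    """Evenly spaced marker map including both ends of every chromosome.

    Markers sit at 0, step, 2*step, ... plus the chromosome end; a step
    larger than the chromosome leaves just the two end markers.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if len(chrom_lengths_cM) != n_chrom:
        raise ValueError("chrom_lengths_cM length must equal n_chrom")
    if marker_step_cM <= 0 or any(L <= 0 for L in chrom_lengths_cM):
        raise ValueError("chromosome lengths and marker step must be positive")
    rows = []
    for c in range(1, n_chrom + 1):
        L = float(chrom_lengths_cM[c - 1])
        pos = np.arange(0.0, L, marker_step_cM)
        pos = np.unique(np.append(pos, L))
        for i, p in enumerate(pos, start=1):
            rows.append({"marker": f"C{c}M{i}", "chrom": c, "pos_cM": float(p)})
    return GeneticMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# RIL genotypes
# ---------------------------------------------------------------------------

def simulate_ril_genotypes(gmap: GeneticMap, n_lines: int, seed=None,
                           missing_rate: float = 0.0) -> pd.DataFrame:
    """Simulate homozygous RIL genotypes along the map.

    Per line and chromosome the first marker is A or B with probability 1/2
    and subsequent markers switch with probability ``ril_recomb_fraction(d)``
    for the inter-marker distance d.  Returns a DataFrame indexed by line id
    with one column per marker, values 'A'/'B' (NaN where masked missing).
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if gmap.table.empty:
        raise ValueError("empty genetic map")
    rng = np.random.default_rng(seed)
    cols = {}
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        names = gmap.chrom_markers(chrom)
        R = ril_recomb_fraction(np.diff(pos))
        state = rng.random(n_lines) < 0.5            # True = B
        states = [state]
        for j in range(len(pos) - 1):
            flip = rng.random(n_lines) < R[j]
            state = np.logical_xor(states[-1], flip)
            states.append(state)
        for name, s in zip(names, states):
            cols[name] = np.where(s, "B", "A")
    geno = pd.DataFrame(cols, index=[f"RIL{i + 1:03d}" for i in range(n_lines)])
    geno = geno[gmap.markers]
    geno.index.name = "line_id"
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno = geno.mask(mask)
    return geno


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QTLSpecItem:
    """A planted additive QTL: chromosome, position (cM) and effect ``a``.

    ``a`` is the effect of the A allele relative to the population mean, in
    trait units; homozygous classes differ by 2a.
    """

    chrom: object
    pos_cM: float
    effect: float


def simulate_trait_values(genotypes: pd.DataFrame,
                          gmap: GeneticMap,
                          qtl_spec: Sequence[QTLSpecItem],
                          sigma_line: float,
                          sigma_nucleus: float,
                          n_nuclei_per_line: int,
                          n_plants_per_line: int = 2,
                          seed=None,
                          trait_name: str = "trait") -> tuple[pd.DataFrame, float]:
    """Simulate per-nucleus trait values with a planted variance structure.

    line value  = sum_i a_i x_i + N(0, sigma_line^2),  x_i = +1 (A) / -1 (B)
                  at the marker nearest each planted QTL;
    nucleus value = line value + N(0, sigma_nucleus^2).

    Returns the long trait table (line_id, plant_id, nucleus_id, trait) and
    the ground-truth broad-sense heritability
    (sum a_i^2 + sigma_line^2) / (sum a_i^2 + sigma_line^2 + sigma_nucleus^2)
    using Var(x_i) = 1 for allele frequency 1/2.
    """
    if sigma_line < 0 or sigma_nucleus < 0:
        raise ValueError("sigmas must be >= 0")
    if n_nuclei_per_line < 1 or n_plants_per_line < 1:
        raise ValueError("need >=1 nucleus and >=1 plant per line")
    rng = np.random.default_rng(seed)
    n_lines = len(genotypes)
    genetic = np.zeros(n_lines)
    genetic_var = 0.0
    for q in qtl_spec:
        lo, hi = gmap.span(q.chrom)
        if not (lo <= q.pos_cM <= hi):
            raise ValueError(f"QTL position {q.pos_cM} cM off chromosome {q.chrom!r} [{lo}, {hi}]")
        marker = gmap.nearest_marker(q.chrom, q.pos_cM)
        codes = genotypes[marker]
        x = np.where(codes == "A", 1.0, np.where(codes == "B", -1.0, 0.0))
        genetic += q.effect * x
        genetic_var += q.effect ** 2
    line_values = genetic + rng.normal(0.0, sigma_line, n_lines)

    rows = []
    for li, (line_id, lv) in enumerate(zip(genotypes.index, line_values)):
        noise = rng.normal(0.0, sigma_nucleus, n_nuclei_per_line)
        for k in range(n_nuclei_per_line):
            rows.append({
                "line_id": line_id,
                "plant_id": f"P{(k % n_plants_per_line) + 1}",
                "nucleus_id": k + 1,
                trait_name: lv + noise[k],
            })
    table = pd.DataFrame(rows)
    total = genetic_var + sigma_line ** 2 + sigma_nucleus ** 2
    true_bsh = (genetic_var + sigma_line ** 2) / total if total > 0 else 0.0
    return table, float(true_bsh)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusTruth:
    """Ground truth for one rendered nucleus.

    center/axes/orientation define the nucleus ellipse (pixel units, radians);
    chromocenters is a list of ((row, col), radius_px, intensity) discs that
    must lie inside the ellipse; intensities are mean 8-bit levels and must
    satisfy chromocenter > nucleus > background.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    orientation: float = 0.0
    nucleus_intensity: float = 90.0
    chromocenters: tuple = ()
    background_level: float = 10.0
    noise_sd: float = 2.0

    def __post_init__(self):
        a, b = self.axes
        if a <= 0 or b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if not (self.background_level < self.nucleus_intensity):
            raise ValueError("nucleus intensity must exceed background level")
        for (cc, rad, inten) in self.chromocenters:
            if inten <= self.nucleus_intensity:
                raise ValueError("chromocenter intensity must exceed nucleus intensity")
            if rad <= 0:
                raise ValueError("chromocenter radius must be positive")
            if not self._disc_inside(cc, rad):
                raise ValueError(f"chromocenter at {cc} (r={rad}) not inside nucleus ellipse")

    def _disc_inside(self, cc_center, radius) -> bool:
        # conservative: the disc centre must fit the ellipse shrunk by the radius
        a, b = self.axes
        if radius >= min(a, b):
            return False
        dy = cc_center[0] - self.center[0]
        dx = cc_center[1] - self.center[1]
        ct, st = math.cos(self.orientation), math.sin(self.orientation)
        u = dy * ct + dx * st
        v = -dy * st + dx * ct
        return (u / (a - radius)) ** 2 + (v / (b - radius)) ** 2 <= 1.0


def render_nucleus_image(truths: Sequence[NucleusTruth],
                         image_shape: tuple[int, int],
                         seed=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render nuclei to an 8-bit image plus exact ground-truth label masks.

    Returns (image uint8, nucleus label mask uint16, chromocenter label mask
    uint16).  Chromocenter labels are numbered in nucleus order.  Nuclei must
    not overlap (fields of spread nuclei) and must fit in the frame; all
    truths must share background_level and noise_sd.
    """
    if not truths:
        raise ValueError("need at least one nucleus truth")
    bg = truths[0].background_level
    noise_sd = truths[0].noise_sd
    if any(t.background_level != bg or t.noise_sd != noise_sd for t in truths):
        raise ValueError("all truths in a field must share background_level and noise_sd")
    rng = np.random.default_rng(seed)
    img = np.full(image_shape, float(bg))
    nuc_mask = np.zeros(image_shape, dtype=np.uint16)
    cc_mask = np.zeros(image_shape, dtype=np.uint16)
    cc_label = 0
    for i, t in enumerate(truths, start=1):
        rr, cc = _draw_ellipse(t.center[0], t.center[1], t.axes[0], t.axes[1],
                               shape=None, rotation=-t.orientation)
        if rr.size == 0:
            raise ValueError("degenerate nucleus ellipse")
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= image_shape[0] or cc.max() >= image_shape[1]:
            raise ValueError(f"nucleus {i} does not fit inside the image")
        if np.any(nuc_mask[rr, cc] != 0):
            raise ValueError(f"nucleus {i} overlaps a previous nucleus")
        nuc_mask[rr, cc] = i
        img[rr, cc] = t.nucleus_intensity
        for (center, radius, inten) in t.chromocenters:
            cc_label += 1
            r2, c2 = _draw_disk(center, radius, shape=image_shape)
            cc_mask[r2, c2] = cc_label
            img[r2, c2] = inten
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, image_shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, nuc_mask, cc_mask


def random_nucleus_field(n_nuclei: int,
                         image_shape: tuple[int, int] = (512, 512),
                         seed=None,
                         n_cc_range: tuple[int, int] = (6, 10),
                         axes_range: tuple[float, float] = (26.0, 40.0),
                         nucleus_intensity: float = 90.0,
                         cc_delta: float = 80.0,
                         cc_radius_range: tuple[float, float] = (2.5, 4.0),
                         background_level: float = 10.0,
                         noise_sd: float = 2.0) -> list[NucleusTruth]:
    """Place non-overlapping random nuclei on a jittered grid.

    Defaults emulate underexposed DAPI fields: background ~4% of the 8-bit
    range, nuclei ~35% of it, chromocenters ~80 levels brighter, and 6-10
    chromocenters per nucleus (leaf interphase nuclei typically show 8-10);
    chromocenters cover well under 10% of the nucleus area, as in nuclei with
    a moderate heterochromatin fraction.
    """
    rng = np.random.default_rng(seed)
    n_side = math.ceil(math.sqrt(n_nuclei))
    cell_h = image_shape[0] / n_side
    cell_w = image_shape[1] / n_side
    max_ax = max(axes_range)
    if cell_h < 2 * max_ax + 4 or cell_w < 2 * max_ax + 4:
        raise ValueError("image too small for the requested number of nuclei")
    truths = []
    order = rng.permutation(n_side * n_side)[:n_nuclei]
    for k in order:
        gi, gj = divmod(int(k), n_side)
        a = rng.uniform(*axes_range)
        b = rng.uniform(*axes_range)
        margin_r = cell_h / 2 - max(a, b) - 2
        margin_c = cell_w / 2 - max(a, b) - 2
        cy = (gi + 0.5) * cell_h + rng.uniform(-margin_r, margin_r)
        cx = (gj + 0.5) * cell_w + rng.uniform(-margin_c, margin_c)
        theta = rng.uniform(0, math.pi)
        n_cc = int(rng.integers(n_cc_range[0], n_cc_range[1] + 1))
        ccs = []
        attempts = 0
        while len(ccs) < n_cc and attempts < 200:
            attempts += 1
            rad = rng.uniform(*cc_radius_range)
            # sample inside the shrunk ellipse in its own frame
            u = rng.uniform(-1, 1) * (a - rad - 1)
            v = rng.uniform(-1, 1) * (b - rad - 1)
            if (u / (a - rad - 1)) ** 2 + (v / (b - rad - 1)) ** 2 > 0.85:
                continue
            ct, st = math.cos(theta), math.sin(theta)
            pr = cy + u * ct - v * st
            pc = cx + u * st + v * ct
            # keep discs >=3 px apart so rendered blobs stay 8-disconnected
            if any((pr - p[0][0]) ** 2 + (pc - p[0][1]) ** 2 < (rad + p[1] + 3) ** 2
                   for p in ccs):
                continue
            ccs.append(((pr, pc), rad, nucleus_intensity + cc_delta))
        truths.append(NucleusTruth(center=(cy, cx), axes=(a, b), orientation=theta,
                                   nucleus_intensity=nucleus_intensity,
                                   chromocenters=tuple(ccs),
                                   background_level=background_level,
                                   noise_sd=noise_sd))
    return truths
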
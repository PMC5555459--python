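"""Composite interval mapping (CIM) for selfed RIL populations.

The scan is Haley-Knott regression on expected genotype scores: at each grid
position the per-line probability of carrying the A allele is computed from
the nearest non-missing flanking markers (Haldane map function, selfed-RIL
transform R = 2r/(1+2r)), and the phenotype (per-line means) is regressed on
the score 2*P(A)-1 plus the active background cofactors.  Cofactors come
from forward/backward stepwise regression on the marker codes and are
deactivated within a +/-10 cM window around the tested position, the
classic CIM scheme.  Significance is assessed by a genome-wide permutation
threshold (the 95th percentile of maximum LOD over phenotype permutations).

At a position the model comparison is

    LOD = (n/2) * log10(RSS_reduced / RSS_full)

where the reduced model omits the genotype score.  ADD is the fitted
coefficient of the score, i.e. the A-allele (first-parent) effect relative
to the population mean; homozygous class means differ by 2*ADD.  R2 is the
variance explained by the genotype term, by default as a percentage of the
total phenotypic variance of the line means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import GeneticMap, ril_recomb_fraction

__all__ = ["CIMConfig", "ProbGrid", "LODProfile", "QTLCall",
           "genotype_probs", "select_cofactors", "cim_scan",
           "permutation_threshold", "call_qtl", "colocate"]

_TOL = 1e-10


@dataclass(frozen=True)
class CIMConfig:
    """CIM parameters: 10 cM cofactor window, stepwise entry/exit p-values
    of 0.05, 1 cM walking step and a 1000-permutation 5% genome-wide
    threshold by default."""

    window_cM: float = 10.0
    p_in: float = 0.05
    p_out: float = 0.05
    step_cM: float = 1.0
    n_permutations: int = 1000
    alpha: float = 0.05
    max_cofactors: Optional[int] = None
    seed: Optional[int] = None
    r2_denominator: str = "tss"   # 'tss' or 'reduced'

    def __post_init__(self):
        if self.window_cM <= 0 or self.step_cM <= 0:
            raise ValueError("window_cM and step_cM must be positive")
        if not (0 < self.p_in < 1 and 0 < self.p_out < 1):
            raise ValueError("p_in and p_out must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.r2_denominator not in ("tss", "reduced"):
            raise ValueError("r2_denominator must be 'tss' or 'reduced'")


@dataclass
class ProbGrid:
    """Evaluation grid with per-line P(A) and imputed marker scores.

    prob[i, j] is line i's probability of carrying the A allele at grid
    position j; at an observed, non-missing marker it is the 0/1 indicator.
    marker_scores holds 2*P(A)-1 at the marker positions themselves
    (exactly +/-1 where observed), used for cofactor selection.
    """

    gmap: GeneticMap
    line_ids: list
    chrom: np.ndarray          # per grid position
    pos: np.ndarray            # cM, per grid position
    prob: np.ndarray           # (n_lines, n_positions)
    marker_names: list[str]
    marker_chrom: np.ndarray
    marker_pos: np.ndarray
    marker_scores: np.ndarray  # (n_lines, n_markers)

    @property
    def scores(self) -> np.ndarray:
        """Expected genotype score 2*P(A) - 1 at every grid position."""
        return 2.0 * self.prob - 1.0


@dataclass
class LODProfile:
    """Per-position LOD, additive effect and explained variance (%)."""

    chrom: np.ndarray
    pos: np.ndarray
    lod: np.ndarray
    add: np.ndarray
    r2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos_cM": self.pos,
                             "lod": self.lod, "add": self.add, "r2": self.r2})


@dataclass(frozen=True)
class QTLCall:
    """One called QTL: the contiguous above-threshold interval, its peak
    position, and the LOD/ADD/R2 values at the peak."""

    trait: Optional[str]
    chrom: object
    start: float
    end: float
    top: float
    lod: float
    add: float
    r2: float
    map_name: Optional[str] = None


# ---------------------------------------------------------------------------
# conditional genotype probabilities
# ---------------------------------------------------------------------------

def _codes_matrix(genotypes: pd.DataFrame, markers: Sequence[str]) -> np.ndarray:
    g = genotypes[list(markers)].to_numpy()
    out = np.full(g.shape, np.nan)
    out[g == "A"] = 1.0
    out[g == "B"] = -1.0
    return out


def _conditional_pA(p_obs: np.ndarray, s_obs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """P(A at each target position | observed flanking marker states).

    The genotype along the chromosome is treated as a two-state Markov chain
    with switch probability ril_recomb_fraction(d) per segment; the
    conditional given both flanks is the two-segment chain ratio.
    """
    pA = np.empty(len(targets))
    idx = np.searchsorted(p_obs, targets)
    exact = (idx < len(p_obs)) & (p_obs[np.minimum(idx, len(p_obs) - 1)] == targets)
    right_only = (idx == 0) & ~exact
    left_only = idx == len(p_obs)
    both = ~exact & ~right_only & ~left_only

    if exact.any():
        pA[exact] = (s_obs[idx[exact]] > 0).astype(float)
    if left_only.any():
        d = targets[left_only] - p_obs[-1]
        R = ril_recomb_fraction(d)
        pA[left_only] = np.where(s_obs[-1] > 0, 1.0 - R, R)
    if right_only.any():
        d = p_obs[0] - targets[right_only]
        R = ril_recomb_fraction(d)
        pA[right_only] = np.where(s_obs[0] > 0, 1.0 - R, R)
    if both.any():
        li = idx[both] - 1
        ri = idx[both]
        dL = targets[both] - p_obs[li]
        dR = p_obs[ri] - targets[both]
        RL = ril_recomb_fraction(dL)
        RR = ril_recomb_fraction(dR)
        tL_A = np.where(s_obs[li] > 0, 1.0 - RL, RL)   # P(state_L -> A)
        tR_A = np.where(s_obs[ri] > 0, 1.0 - RR, RR)   # P(A -> state_R)
        num = tL_A * tR_A
        den = num + (1.0 - tL_A) * (1.0 - tR_A)
        pA[both] = num / den
    return pA


def genotype_probs(gmap: GeneticMap, genotypes: pd.DataFrame,
                   step_cM: float = 1.0) -> ProbGrid:
    """Conditional P(A) on a cM grid plus imputed scores at the markers."""
    if step_cM <= 0:
        raise ValueError("step_cM must be positive")
    line_ids = list(genotypes.index)
    n = len(line_ids)
    grid_chrom, grid_pos = [], []
    for chrom in gmap.chromosomes:
        p = gmap.positions(chrom)
        g = np.unique(np.append(np.arange(p[0], p[-1], step_cM), p[-1]))
        grid_chrom.extend([chrom] * len(g))
        grid_pos.append(g)
    grid_pos = np.concatenate(grid_pos)
    grid_chrom = np.asarray(grid_chrom, dtype=object)

    prob = np.empty((n, len(grid_pos)))
    marker_names = gmap.markers
    marker_chrom = gmap.table["chrom"].to_numpy(dtype=object)
    marker_pos = gmap.table["pos_cM"].to_numpy(dtype=float)
    marker_scores = np.empty((n, len(marker_names)))

    for chrom in gmap.chromosomes:
        p_m = gmap.positions(chrom)
        codes = _codes_matrix(genotypes, gmap.chrom_markers(chrom))
        gsel = np.flatnonzero(grid_chrom == chrom)
        msel = np.flatnonzero(marker_chrom == chrom)
        targets = grid_pos[gsel]
        for i in range(n):
            obs = np.flatnonzero(~np.isnan(codes[i]))
            if len(obs) == 0:
                warnings.warn(f"line {line_ids[i]} has no genotype on chromosome "
                              f"{chrom!r}; probabilities set to 1/2", stacklevel=2)
                prob[i, gsel] = 0.5
                marker_scores[i, msel] = 0.0
                continue
            p_obs, s_obs = p_m[obs], codes[i, obs]
            prob[i, gsel] = _conditional_pA(p_obs, s_obs, targets)
            marker_scores[i, msel] = 2.0 * _conditional_pA(p_obs, s_obs, p_m) - 1.0

    return ProbGrid(gmap=gmap, line_ids=line_ids, chrom=grid_chrom, pos=grid_pos,
                    prob=prob, marker_names=marker_names, marker_chrom=marker_chrom,
                    marker_pos=marker_pos, marker_scores=marker_scores)


# ---------------------------------------------------------------------------
# stepwise cofactor selection
# ---------------------------------------------------------------------------

def _phenotype_vector(prob_grid: ProbGrid, phenotype) -> np.ndarray:
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(prob_grid.line_ids).to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("phenotype missing for some lines of the grid")
        return y
    y = np.asarray(phenotype, dtype=float)
    if len(y) != len(prob_grid.line_ids):
        raise ValueError("phenotype length does not match the number of lines")
    return y


def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values for the non-intercept columns of [1 | X]."""
    n = len(y)
    Z = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    df = n - Z.shape[1]
    if df <= 0 or rank < Z.shape[1]:
        return np.full(X.shape[1], np.nan)
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.diag(cov)[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1:] / se
    return 2.0 * stats.t.sf(np.abs(t), df)


def select_cofactors(prob_grid: ProbGrid, phenotype, config: CIMConfig = CIMConfig()
                     ) -> list[str]:
    """Forward/backward stepwise selection of background markers.

    Forward: add the marker with the smallest partial-F p-value while it is
    below ``p_in``; after every addition, backward-drop included markers
    whose p-value exceeds ``p_out``.  Deterministic: ties go to the smaller
    p-value then the lower marker index; collinear candidates are skipped.
    The number of cofactors is capped at floor(sqrt(n_lines)) unless
    ``max_cofactors`` is set.
    """
    y = _phenotype_vector(prob_grid, phenotype)
    n = len(y)
    X = prob_grid.marker_scores
    m = X.shape[1]
    if np.std(y) == 0:
        return []
    max_cof = config.max_cofactors or int(math.floor(math.sqrt(n)))
    included: list[int] = []

    while len(included) < max_cof:
        # forward step on the residualized candidates
        Z = np.column_stack([np.ones(n)] + [X[:, j] for j in included])
        Q, _ = np.linalg.qr(Z)
        ry = y - Q @ (Q.T @ y)
        RX = X - Q @ (Q.T @ X)
        d = np.einsum("ij,ij->j", RX, RX)
        s = RX.T @ ry
        df = n - Z.shape[1] - 1
        if df <= 0:
            break
        rss0 = ry @ ry
        with np.errstate(divide="ignore", invalid="ignore"):
            ess = s * s / d
            F = ess / ((rss0 - ess) / df)
        p = stats.f.sf(F, 1, df)
        p[~np.isfinite(p)] = np.inf
        p[d <= _TOL * n] = np.inf
        if included:
            p[np.asarray(included, dtype=int)] = np.inf
        best = int(np.argmin(p))          # argmin takes the lowest index on ties
        if not np.isfinite(p[best]) or p[best] >= config.p_in:
            break
        included.append(best)
        # backward sweep
        while len(included) > 1:
            pv = _ols_pvalues(X[:, included], y)
            if np.isnan(pv).all():
                break
            worst = int(np.nanargmax(pv))
            if pv[worst] <= config.p_out:
                break
            del included[worst]
    return [prob_grid.marker_names[j] for j in included]


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def cim_scan(prob_grid: ProbGrid, phenotype, cofactors: Sequence[str],
             config: CIMConfig = CIMConfig()) -> LODProfile:
    """Composite-interval-mapping LOD/ADD/R2 profile.

    Cofactors within ``window_cM`` of the tested position on the same
    chromosome are deactivated there.  Positions where the model would have
    fewer than 3 residual degrees of freedom are skipped (NaN) with a
    warning.
    """
    y = _phenotype_vector(prob_grid, phenotype)
    n = len(y)
    n_pos = len(prob_grid.pos)
    lod = np.zeros(n_pos)
    add = np.zeros(n_pos)
    r2 = np.zeros(n_pos)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return LODProfile(prob_grid.chrom, prob_grid.pos, lod, add, r2)

    name_to_idx = {nm: j for j, nm in enumerate(prob_grid.marker_names)}
    cof_idx = [name_to_idx[c] for c in cofactors]
    Xg = prob_grid.scores

    # per-cofactor exclusion pattern across positions, packed into group keys
    if cof_idx:
        excl = np.zeros((len(cof_idx), n_pos), dtype=bool)
        for k, j in enumerate(cof_idx):
            same = prob_grid.chrom == prob_grid.marker_chrom[j]
            excl[k] = same & (np.abs(prob_grid.pos - prob_grid.marker_pos[j])
                              <= config.window_cM)
        keys = np.zeros(n_pos, dtype=np.int64)
        for k in range(len(cof_idx)):
            keys |= excl[k].astype(np.int64) << k
    else:
        keys = np.zeros(n_pos, dtype=np.int64)

    skipped = False
    for key in np.unique(keys):
        sel = np.flatnonzero(keys == key)
        active = [cof_idx[k] for k in range(len(cof_idx)) if not (key >> k) & 1]
        if n <= len(active) + 3:
            lod[sel] = add[sel] = r2[sel] = np.nan
            skipped = True
            continue
        Z = np.column_stack([np.ones(n)] + [prob_grid.marker_scores[:, j] for j in active])
        Q, _ = np.linalg.qr(Z)
        ry = y - Q @ (Q.T @ y)
        rss_red = float(ry @ ry)
        G = Xg[:, sel]
        RG = G - Q @ (Q.T @ G)
        d = np.einsum("ij,ij->j", RG, RG)
        s = RG.T @ ry
        ok = d > _TOL * n
        ess = np.zeros(len(sel))
        beta = np.zeros(len(sel))
        ess[ok] = s[ok] ** 2 / d[ok]
        beta[ok] = s[ok] / d[ok]
        rss_full = np.maximum(rss_red - ess, np.finfo(float).tiny)
        with np.errstate(divide="ignore"):
            lod[sel] = np.where(ok & (rss_red > 0),
                                (n / 2.0) * np.log10(rss_red / rss_full), 0.0)
        add[sel] = beta
        denom = tss if config.r2_denominator == "tss" else rss_red
        r2[sel] = 100.0 * ess / denom
    if skipped:
        warnings.warn("some positions skipped: too few lines for the active "
                      "cofactor set", stacklevel=2)
    return LODProfile(prob_grid.chrom, prob_grid.pos, lod, add, r2)


# ---------------------------------------------------------------------------
# permutation threshold
# ---------------------------------------------------------------------------

def permutation_threshold(prob_grid: ProbGrid, phenotype,
                          config: CIMConfig = CIMConfig(),
                          reselect_cofactors: bool = True,
                          return_distribution: bool = False):
    """Genome-wide LOD threshold from phenotype permutations.

    For each permutation the phenotype is shuffled across lines, cofactors
    are re-selected (unless ``reselect_cofactors`` is False — faster but
    approximate) and the genome-wide maximum LOD recorded; the threshold is
    the empirical (1 - alpha) quantile of those maxima.
    """
    if config.n_permutations < 20:
        raise ValueError("need at least 20 permutations for a stable percentile")
    y = _phenotype_vector(prob_grid, phenotype)
    rng = np.random.default_rng(config.seed)
    fixed_cof = None
    if not reselect_cofactors:
        fixed_cof = select_cofactors(prob_grid, y, config)
    max_lods = np.empty(config.n_permutations)
    for i in range(config.n_permutations):
        yp = rng.permutation(y)
        cof = fixed_cof if fixed_cof is not None else select_cofactors(prob_grid, yp, config)
        prof = cim_scan(prob_grid, yp, cof, config)
        finite = prof.lod[np.isfinite(prof.lod)]
        max_lods[i] = finite.max() if finite.size else 0.0
    threshold = float(np.quantile(max_lods, 1.0 - config.alpha))
    if return_distribution:
        return threshold, max_lods
    return threshold


# ---------------------------------------------------------------------------
# calling and colocation
# ---------------------------------------------------------------------------

def call_qtl(profile: LODProfile, threshold: float,
             trait: Optional[str] = None, map_name: Optional[str] = None
             ) -> list[QTLCall]:
    """Contiguous above-threshold runs of the profile as QTL calls.

    Runs never span chromosomes; the peak is the leftmost maximum of the
    run and supplies the reported LOD/ADD/R2.
    """
    calls = []
    above = np.isfinite(profile.lod) & (profile.lod >= threshold)
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and profile.chrom[j + 1] == profile.chrom[i]:
            j += 1
        run = slice(i, j + 1)
        k = i + int(np.argmax(profile.lod[run]))
        calls.append(QTLCall(trait=trait, chrom=profile.chrom[i],
                             start=float(profile.pos[i]), end=float(profile.pos[j]),
                             top=float(profile.pos[k]), lod=float(profile.lod[k]),
                             add=float(profile.add[k]), r2=float(profile.r2[k]),
                             map_name=map_name))
        i = j + 1
    return calls


def colocate(call_a: QTLCall, call_b: QTLCall) -> tuple[bool, Optional[tuple[float, float]]]:
    """Whether two calls overlap on the same chromosome; closed intervals."""
    if call_a.map_name is not None and call_b.map_name is not None \
            and call_a.map_name != call_b.map_name:
        raise ValueError("calls come from different genetic maps")
    if call_a.chrom != call_b.chrom:
        return False, None
    lo = max(call_a.start, call_b.start)
    hi = min(call_a.end, call_b.end)
    if lo > hi:
        return False, None
    return True, (lo, hi)
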
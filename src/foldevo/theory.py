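"""Mutation-selection statistical mechanics of the stability landscape.

In the monomorphic limit the origin-fixation Moran chain is reversible and
its stationary law over sequences is a Boltzmann measure,

    P(seq)  ~  pi_HKY(seq) * f(seq)**(N-1),

where pi_HKY is the stationary sequence measure of the mutation process
and population size plays the role of an inverse temperature (the exponent
N-1 is what the implemented Moran fixation probability yields through the
identity p_fix(r)/p_fix(1/r) = r**(N-1)).  Projected on the two stability
coordinates (x, y) this becomes

    P(x, y)  ~  exp[ (N-1) * log f(x, y) + S(x, y) ],

with S the *mutational entropy*: the log-density of (x, y) under mutation
alone, the entropic force pulling stabilities toward what random sequences
typically achieve.  The maximizers (x*, y*) of the exponent Phi solve the
maximum-likelihood equations and predict the stationary mean stabilities
when the distribution is narrowly peaked.

This module estimates S by sampling the mutation-only measure, maximizes
Phi numerically, provides the *exact* stationary distribution of the
origin-fixation chain on enumerable toy genes as an oracle for the
analytic form, fits the optimal GC usage from fitness-versus-GC scans, and
quantifies whether fitness differences between mutation biases are large
enough (N * |Delta log f| > 1) to be selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .evolution import (EvolutionRun, EvolveResult, HKYModel, evolve,
                        moran_fixation_probability)
from .sequences import (CODONS, CodingSequence, STANDARD_CODE,
                        hky_stationary_codon_distribution)
from .stability import (EnergyModel, FitnessSpec, StabilityCalculator,
                        StabilityPair, additive_fitness, fitness as fitness_fn,
                        normalized_stabilities, protein_indices)
from .structure import ContactMap

PopExponent = Literal["N-1", "N"]


def _pop_factor(N: int, pop_exponent: PopExponent) -> float:
    return float(N - 1) if pop_exponent == "N-1" else float(N)


# --------------------------------------------------------------------------
# Mutation-only sampling

def batch_stabilities(aa: np.ndarray, cmap: ContactMap, model: EnergyModel,
                      chunk: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (dG_unf, alpha_gap) for many sequences on one map.

    ``aa`` is an (n, L) integer array of amino-acid indices.
    """
    aa = np.asarray(aa)
    n, L = aa.shape
    if L != cmap.L:
        raise ValueError("sequence length != contact-map size")
    pi, pj = cmap.eligible_pairs()
    if len(pi) < 1:
        raise ValueError("no eligible pairs")
    ci, cj = cmap.pairs[:, 0], cmap.pairs[:, 1]
    nc = cmap.n_contacts
    dg = np.empty(n)
    alpha = np.empty(n)
    rem_scale = math.sqrt(2.0 * nc * model.omega * L)
    for s in range(0, n, chunk):
        blk = aa[s:s + chunk]
        e_nat = model.U[blk[:, ci], blk[:, cj]].sum(axis=1) if nc else np.zeros(len(blk))
        vals = model.U[blk[:, pi], blk[:, pj]]
        ubar = vals.mean(axis=1)
        sig = vals.std(axis=1)
        e_rem = nc * ubar - sig * rem_scale
        dg[s:s + chunk] = -(e_nat + model.s_conf * L)
        if model.gap_normalizer == "rem":
            denom = np.abs(e_rem)
        else:
            denom = np.abs(e_nat)
        alpha[s:s + chunk] = (e_rem - e_nat) / denom
    return dg, alpha


def mutation_only_sample(gene: CodingSequence, cmap: ContactMap,
                         model: EnergyModel, hky: HKYModel,
                         n_samples: int, seed: int,
                         fitness_spec: FitnessSpec | None = None,
                         sampler: Literal["stationary", "trajectory"] = "stationary",
                         thin: int = 20) -> np.ndarray:
    """Sample the stability distribution under mutation alone.

    Returns an (n_samples, 2) array of threshold-normalized (x, y) pairs
    (raw (dG_unf, alpha_gap) if no ``fitness_spec`` is given).

    The default ``stationary`` sampler draws codons i.i.d. from the
    HKY-stationary sense-codon measure, which is the exact long-run law of
    the accept-every-non-stop-proposal dynamics; the ``trajectory`` sampler
    runs that dynamics explicitly (recording every ``thin`` proposals after
    an equal-length burn-in) and is kept as a cross-check.
    """
    if n_samples < 1:
        raise ValueError("need n_samples >= 1")
    rng = np.random.default_rng(seed)
    L = cmap.L
    code = gene.code
    aa_of = code.aa_lookup()
    if sampler == "stationary":
        p = hky_stationary_codon_distribution(hky.gc, hky.kappa, code,
                                              exclude_stops=True)
        cod = rng.choice(64, size=(n_samples, L), p=p)
        aa = aa_of[cod]
    elif sampler == "trajectory":
        aa = _mutation_only_trajectory(gene, cmap, hky, n_samples, thin, rng)
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    dg, alpha = batch_stabilities(aa, cmap, model)
    if fitness_spec is None:
        return np.stack([dg, alpha], axis=1)
    x = dg / fitness_spec.dG_threshold
    y = alpha / fitness_spec.alpha_threshold
    return np.stack([x, y], axis=1)


def _mutation_only_trajectory(gene: CodingSequence, cmap: ContactMap,
                              hky: HKYModel, n_samples: int, thin: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Accept every non-stop proposal; record amino-acid states."""
    nt = gene.nt_indices()
    aa_of = gene.code.aa_lookup()
    out = hky.out_rates()
    q = hky.rate_matrix().clip(min=0.0)
    np.fill_diagonal(q, 0.0)
    cond_cum = np.cumsum(q / q.sum(axis=1, keepdims=True), axis=1)
    burn = n_samples * thin // 4 + 10 * len(nt)
    states = np.empty((n_samples, cmap.L), dtype=np.int64)
    got = 0
    step = 0
    site_cum = np.cumsum(out[nt])
    while got < n_samples:
        step += 1
        site = int(np.searchsorted(site_cum, rng.random() * site_cum[-1], side="right"))
        a = nt[site]
        b = int(np.searchsorted(cond_cum[a], rng.random(), side="right"))
        codon = site // 3
        bpos = 3 * codon
        c_new = int(16 * nt[bpos] + 4 * nt[bpos + 1] + nt[bpos + 2]) + (b - a) * 4 ** (2 - site % 3)
        if aa_of[c_new] < 0:
            continue  # stop: nonviable, rejected even without selection
        nt[site] = b
        site_cum = np.cumsum(out[nt])
        if step > burn and step % thin == 0:
            cod = (16 * nt[0::3] + 4 * nt[1::3] + nt[2::3])
            states[got] = aa_of[cod]
            got += 1
    return states


# --------------------------------------------------------------------------
# Mutational entropy

@dataclass
class EntropyEstimate:
    """log-density of (x, y) under mutation alone, on a rectangular grid.

    ``S`` is defined up to an additive constant; cells with no sample are
    masked (``valid`` False, S = -inf).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    S: np.ndarray
    valid: np.ndarray
    gc: float
    kappa: float
    n_samples: int

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        if not (self.x_edges[0] <= x <= self.x_edges[-1]
                and self.y_edges[0] <= y <= self.y_edges[-1]):
            raise ValueError(f"point ({x}, {y}) is off the entropy grid")
        i = min(int(np.searchsorted(self.x_edges, x, side="right")) - 1,
                len(self.x_edges) - 2)
        j = min(int(np.searchsorted(self.y_edges, y, side="right")) - 1,
                len(self.y_edges) - 2)
        return i, j

    def lookup(self, x: float, y: float) -> float:
        i, j = self.cell_of(x, y)
        return float(self.S[i, j])

    def to_frame(self) -> pd.DataFrame:
        xi, yj = np.meshgrid(np.arange(self.S.shape[0]),
                             np.arange(self.S.shape[1]), indexing="ij")
        return pd.DataFrame({
            "x": self.x_centers[xi.ravel()], "y": self.y_centers[yj.ravel()],
            "S": self.S.ravel(), "valid": self.valid.ravel()})


def estimate_entropy(sample: np.ndarray, grid_spec: tuple[int, int] = (40, 40),
                     ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
                     gc: float = float("nan"), kappa: float = float("nan")) -> EntropyEstimate:
    """Histogram estimate of the mutational entropy S(x, y) = log density.

    The additive constant is fixed by normalizing the underlying density to
    integrate to 1 over the grid.  Raises on degenerate (zero-variance)
    samples, for which no two-dimensional density exists.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 2 or sample.shape[1] != 2:
        raise ValueError("sample must be (n, 2)")
    if len(sample) < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(sample[:, 0]) < 1e-12 or np.ptp(sample[:, 1]) < 1e-12:
        raise ValueError("degenerate sample: zero variance in x or y")
    nx, ny = grid_spec
    hist, xe, ye = np.histogram2d(sample[:, 0], sample[:, 1], bins=(nx, ny),
                                  range=ranges, density=True)
    valid = hist > 0
    with np.errstate(divide="ignore"):
        S = np.where(valid, np.log(hist, where=valid,
                                   out=np.full_like(hist, -np.inf)), -np.inf)
    return EntropyEstimate(x_edges=xe, y_edges=ye, S=S, valid=valid,
                           gc=gc, kappa=kappa, n_samples=len(sample))


def tilted_stability_sample(gene: CodingSequence, cmap: ContactMap,
                            model: EnergyModel, hky: HKYModel,
                            fs: FitnessSpec, N: int, n_accept: int = 2000,
                            burn_in: int = 300, replicas: int = 2,
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample (x, y) from the selection-tilted stationary law at size N.

    Runs the origin-fixation dynamics and returns the post-burn-in (x, y)
    records weighted by their residence time (proposals survived), so the
    weighted sample follows the stationary occupancy measure
    ~ pi_mut(x, y) * f(x, y)**(N-1).  Returns (points, weights, N-1), the
    last being the known log-fitness tilt coefficient of the sample --
    the input format of :func:`umbrella_entropy`.
    """
    run = EvolutionRun(N=N, hky=hky, fitness_spec=fs, n_accept_total=n_accept,
                       burn_in=burn_in, replicas=replicas, seed=seed)
    res = evolve(gene, cmap, model, run)
    tr = res.trajectory[res.trajectory.accept_idx >= burn_in]
    xy, w = [], []
    for _, grp in tr.groupby("replica"):
        props = grp["proposal"].to_numpy()
        mean_gap = max((props[-1] - props[0]) // max(len(props) - 1, 1), 1)
        res_t = np.diff(props, append=props[-1] + mean_gap)
        xy.append(grp[["x", "y"]].to_numpy())
        w.append(res_t.astype(float))
    return np.concatenate(xy), np.concatenate(w), float(N - 1)


_LOG_LETHAL = -1e6  # finite stand-in for log f of nonviable cells


def umbrella_entropy(components: Sequence[tuple[np.ndarray, np.ndarray, float]],
                     fs: FitnessSpec,
                     grid_spec: tuple[int, int] = (60, 60),
                     ranges=None, gc: float = float("nan"),
                     kappa: float = float("nan"), max_iter: int = 1000,
                     tol: float = 1e-9) -> EntropyEstimate:
    """Mutational entropy from tilted samples by multi-histogram reweighting.

    The stationary region at moderate-to-large N lies many standard
    deviations into the tail of the mutation-only (x, y) distribution,
    where a direct histogram has no counts.  Because the stationary law at
    population size N is the mutation-only law tilted by exp[(N-1) log f],
    runs at several smaller N probe that tail with a *known* bias, and the
    standard multiple-histogram (WHAM) estimator recovers the unbiased
    log-density S(x, y) wherever any component has counts.

    ``components`` are (points, weights, tilt-coefficient) triples, e.g.
    the mutation-only sample with coefficient 0 plus
    :func:`tilted_stability_sample` outputs.
    """
    from scipy.special import logsumexp

    if not components:
        raise ValueError("need at least one sample component")
    nx, ny = grid_spec
    if ranges is None:
        xlo = min(float(s[:, 0].min()) for s, _, _ in components)
        xhi = max(float(s[:, 0].max()) for s, _, _ in components)
        ylo = min(float(s[:, 1].min()) for s, _, _ in components)
        yhi = max(float(s[:, 1].max()) for s, _, _ in components)
    else:
        (xlo, xhi), (ylo, yhi) = ranges
    xe = np.linspace(xlo, xhi, nx + 1)
    ye = np.linspace(ylo, yhi, ny + 1)
    hists, wtots, coeffs = [], [], []
    for pts, w, c in components:
        h, *_ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(xe, ye), weights=w)
        hists.append(h)
        wtots.append(float(np.sum(w)))
        coeffs.append(float(c))
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    lf = np.array([[additive_fitness(x, y, fs) for y in yc] for x in xc])
    lf = np.where(np.isfinite(lf), lf, _LOG_LETHAL)
    hsum = sum(hists)
    pos = hsum > 0
    log_z = np.zeros(len(components))
    S = np.full((nx, ny), -np.inf)
    for _ in range(max_iter):
        denom = logsumexp(
            np.stack([np.log(wtots[k]) + coeffs[k] * lf - log_z[k]
                      for k in range(len(components))]), axis=0)
        S = np.where(pos, np.log(np.maximum(hsum, 1e-300)) - denom, -np.inf)
        new_z = np.array([logsumexp((S + coeffs[k] * lf)[pos])
                          for k in range(len(components))])
        new_z -= new_z[0]
        if np.max(np.abs(new_z - log_z)) < tol:
            log_z = new_z
            break
        log_z = new_z
    # normalize like a density on the grid
    cell = (xe[1] - xe[0]) * (ye[1] - ye[0])
    S = S - (logsumexp(S[pos]) + math.log(cell))
    return EntropyEstimate(x_edges=xe, y_edges=ye, S=S, valid=pos,
                           gc=gc, kappa=kappa,
                           n_samples=int(sum(len(p) for p, _, _ in components)))


def evolutionary_exponent(x: float, y: float, fs: FitnessSpec, N: int,
                          entropy: EntropyEstimate,
                          pop_exponent: PopExponent = "N-1") -> float:
    """Phi(x, y) = (N-1) * log f(x, y) + S(x, y).

    Minus Phi is the evolutionary free energy; population size is the
    inverse temperature.  The prefactor is switchable between N-1 (the
    Moran value implemented here) and N.
    """
    return _pop_factor(N, pop_exponent) * additive_fitness(x, y, fs) + entropy.lookup(x, y)


# --------------------------------------------------------------------------
# Maximum-likelihood solution

@dataclass
class MLSolution:
    """Maximizer of the evolutionary exponent Phi on the entropy grid."""

    x_star: float
    y_star: float
    phi_star: float
    hessian_ok: bool
    boundary: bool
    covariance: np.ndarray | None = None


def ml_solve(fs: FitnessSpec, N: int, entropy: EntropyEstimate,
             pop_exponent: PopExponent = "N-1") -> MLSolution:
    """Maximize Phi = (N-1) log f + S over the entropy grid.

    Grid argmax over valid cells, refined by a local quadratic fit over the
    3x3 neighborhood when it is fully valid; the quadratic's Hessian must
    be negative definite for a genuine interior maximum, in which case the
    Gaussian approximation's covariance -H^{-1} is reported.  An argmax on
    the boundary of the sampled region is flagged, not silently returned as
    an interior solution.
    """
    xc, yc = entropy.x_centers, entropy.y_centers
    nf = _pop_factor(N, pop_exponent)
    phi = np.full_like(entropy.S, -np.inf)
    for i, xv in enumerate(xc):
        for j, yv in enumerate(yc):
            if not entropy.valid[i, j]:
                continue
            la = additive_fitness(xv, yv, fs)
            if la == float("-inf"):
                continue
            phi[i, j] = nf * la + entropy.S[i, j]
    if not np.isfinite(phi).any():
        raise ValueError("entropy grid does not cover the viable region")
    i, j = np.unravel_index(np.argmax(phi), phi.shape)
    nx, ny = phi.shape
    boundary = i in (0, nx - 1) or j in (0, ny - 1)
    x_star, y_star, phi_star = float(xc[i]), float(yc[j]), float(phi[i, j])
    hessian_ok = False
    cov = None
    if not boundary and np.isfinite(phi[i - 1:i + 2, j - 1:j + 2]).all():
        # quadratic fit phi ~ a x^2 + b y^2 + c xy + d x + e y + f on 3x3
        dx = xc[i + 1] - xc[i]
        dy = yc[j + 1] - yc[j]
        pts = []
        vals = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                u, v = di * dx, dj * dy
                pts.append([u * u, v * v, u * v, u, v, 1.0])
                vals.append(phi[i + di, j + dj])
        coef, *_ = np.linalg.lstsq(np.array(pts), np.array(vals), rcond=None)
        a, b, c, d, e, _f = coef
        H = np.array([[2 * a, c], [c, 2 * b]])
        eig = np.linalg.eigvalsh(H)
        if np.all(eig < 0):
            hessian_ok = True
            cov = -np.linalg.inv(H)
            du, dv = np.linalg.solve(H, [-d, -e])
            # keep the refinement inside the center cell
            if abs(du) <= dx and abs(dv) <= dy:
                x_star += float(du)
                y_star += float(dv)
                phi_star = float(a * du * du + b * dv * dv + c * du * dv
                                 + d * du + e * dv + _f)
    return MLSolution(x_star=x_star, y_star=y_star, phi_star=phi_star,
                      hessian_ok=hessian_ok, boundary=boundary, covariance=cov)


# --------------------------------------------------------------------------
# Exact stationary distribution on toy systems

@dataclass
class StationaryResult:
    """Exact vs analytic stationary law of the origin-fixation chain."""

    sequences: list[str]
    exact: np.ndarray
    analytic: np.ndarray
    total_variation: float
    fitness_values: np.ndarray


def enumerate_stationary(gene_template: CodingSequence, cmap: ContactMap,
                         model: EnergyModel, hky: HKYModel, fs: FitnessSpec,
                         N: int, pop_exponent: PopExponent = "N-1") -> StationaryResult:
    """Exact stationary vector of the origin-fixation chain on a toy gene.

    Enumerates all 4**(3*n_codons) nucleotide sequences (n_codons <= 3),
    keeps the viable ones (no stop, fitness > 0), builds the uniformized
    transition matrix P = I + Q/Lambda with rates
    q_HKY(a -> b) * p_fix(f'/f) -- the chain whose stationary law the
    reversibility identity p_fix(r)/p_fix(1/r) = r**(N-1) pins down --
    and solves for its stationary vector.  Also returns the analytic
    prediction pi_HKY(seq) * f(seq)**(N-1) (normalized over viable
    sequences) and the total-variation distance between the two.
    """
    n_codons = gene_template.n_codons
    if n_codons > 3:
        raise ValueError("toy enumeration limited to <= 3 codons")
    if n_codons != cmap.L:
        raise ValueError("gene length (codons) must equal contact-map size")
    code = gene_template.code
    aa_of = code.aa_lookup()
    n_nt = 3 * n_codons
    n_seq = 4 ** n_nt
    pi_nt = hky.pi
    q = hky.rate_matrix().clip(min=0.0)
    np.fill_diagonal(q, 0.0)

    # enumerate: sequence index = base-4 expansion, most significant first
    digits = ((np.arange(n_seq)[:, None] // (4 ** np.arange(n_nt - 1, -1, -1)[None, :])) % 4)
    cod = (16 * digits[:, 0::3] + 4 * digits[:, 1::3] + digits[:, 2::3])
    aa = aa_of[cod]
    viable_mask = (aa >= 0).all(axis=1)
    fit = np.zeros(n_seq)
    if viable_mask.any():
        dg, al = batch_stabilities(aa[viable_mask].reshape(-1, cmap.L), cmap, model)
        x = dg / fs.dG_threshold
        y = al / fs.alpha_threshold
        fv = np.array([fitness_fn(xi, yi, fs) for xi, yi in zip(x, y)])
        fit[viable_mask] = fv
    viable_mask &= fit > 0
    vidx = np.where(viable_mask)[0]
    if len(vidx) == 0:
        raise ValueError("no viable sequence in the toy space")
    pos_of = {int(s): k for k, s in enumerate(vidx)}
    nv = len(vidx)

    lam = n_nt * q.sum(axis=1).max() * 1.01  # uniformization constant
    P = np.zeros((nv, nv))
    for k, s in enumerate(vidx):
        f_s = fit[s]
        for site in range(n_nt):
            a = digits[s, site]
            off = 4 ** (n_nt - 1 - site)
            for b in range(4):
                if b == a or q[a, b] == 0.0:
                    continue
                t = s + (b - a) * off
                if not viable_mask[t]:
                    continue
                pfix = moran_fixation_probability(f_s, fit[t], N)
                P[k, pos_of[int(t)]] += q[a, b] * pfix / lam
        P[k, k] = 1.0 - P[k].sum() + P[k, k]

    # stationary vector: solve pi (P - I) = 0 with normalization
    A = P.T - np.eye(nv)
    A[-1, :] = 1.0
    rhs = np.zeros(nv)
    rhs[-1] = 1.0
    exact = np.linalg.solve(A, rhs)
    exact = np.clip(exact, 0.0, None)
    exact /= exact.sum()

    log_pi_hky = np.log(pi_nt)[digits[vidx]].sum(axis=1)
    nf = _pop_factor(N, pop_exponent)
    log_an = log_pi_hky + nf * np.log(fit[vidx])
    log_an -= log_an.max()
    analytic = np.exp(log_an)
    analytic /= analytic.sum()

    seq_strings = ["".join("ACGT"[d] for d in digits[s]) for s in vidx]
    tv = 0.5 * float(np.abs(exact - analytic).sum())
    return StationaryResult(sequences=seq_strings, exact=exact,
                            analytic=analytic, total_variation=tv,
                            fitness_values=fit[vidx])


# --------------------------------------------------------------------------
# Optimal GC usage

@dataclass
class GCOptimum:
    """Optimal GC usage from a cubic fit of mean fitness versus GC."""

    gc_opt: float
    boundary: bool
    coefficients: np.ndarray  # np.polyfit order (highest first)
    fitted_max: float
    r_squared: float

    def predict(self, gc: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, gc)


def optimal_gc(scan: Sequence[tuple[float, float, float]] | pd.DataFrame) -> GCOptimum:
    """Fit mean fitness versus GC usage to a cubic and locate its maximum.

    ``scan`` rows are (gc, mean_fitness, sem).  The optimum is the interior
    root of the fitted derivative at which the cubic has a maximum; if the
    fit is monotone on the scanned interval the boundary GC with the
    largest fitted value is returned with ``boundary=True``.
    """
    if isinstance(scan, pd.DataFrame):
        gc = scan["gc"].to_numpy(dtype=float)
        f = scan["mean_fitness"].to_numpy(dtype=float)
    else:
        arr = np.array([(g, m) for g, m, *_ in scan], dtype=float)
        gc, f = arr[:, 0], arr[:, 1]
    if len(gc) < 4:
        raise ValueError("need at least 4 scan points for a cubic fit")
    if np.ptp(gc) < 1e-12:
        raise ValueError("degenerate scan: all GC values equal")
    coeffs = np.polyfit(gc, f, 3)
    pred = np.polyval(coeffs, gc)
    ss_res = float(((f - pred) ** 2).sum())
    ss_tot = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    deriv = np.polyder(coeffs)
    lo, hi = float(gc.min()), float(gc.max())
    candidates = []
    for root in np.roots(deriv):
        if abs(root.imag) > 1e-9:
            continue
        r = float(root.real)
        if lo < r < hi and np.polyval(np.polyder(deriv), r) < 0:
            candidates.append(r)
    if candidates:
        best = max(candidates, key=lambda r: np.polyval(coeffs, r))
        return GCOptimum(gc_opt=best, boundary=False, coefficients=coeffs,
                         fitted_max=float(np.polyval(coeffs, best)), r_squared=r2)
    end = max((lo, hi), key=lambda g: np.polyval(coeffs, g))
    return GCOptimum(gc_opt=end, boundary=True, coefficients=coeffs,
                     fitted_max=float(np.polyval(coeffs, end)), r_squared=r2)


def scan_gc(gene: CodingSequence, cmap: ContactMap, model: EnergyModel,
            run: EvolutionRun, gc_values: Sequence[float] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 2)),
            ) -> tuple[pd.DataFrame, GCOptimum]:
    """Run the evolutionary dynamics over a GC grid and fit the optimum.

    The fitness thresholds (anchored to the reference protein) and all
    other run parameters are held fixed; only the mutation bias varies.
    Returns the scan table (one row per GC with means and SEMs) and the
    cubic-fit optimum.
    """
    rows = []
    for gc in gc_values:
        r = EvolutionRun(N=run.N, hky=HKYModel(gc=float(gc), kappa=run.hky.kappa),
                         fitness_spec=run.fitness_spec,
                         n_accept_total=run.n_accept_total, burn_in=run.burn_in,
                         replicas=run.replicas, seed=run.seed,
                         max_proposals=run.max_proposals)
        res = evolve(gene, cmap, model, r)
        row = {"gc": float(gc)}
        for fld in ("fitness", "log_fitness", "dG_unf", "alpha_gap", "x", "y", "gc3"):
            row[f"mean_{fld}"] = res.summary[fld]["mean"]
            row[f"sem_{fld}"] = res.summary[fld]["sem"]
        rows.append(row)
    scan = pd.DataFrame(rows)
    opt = optimal_gc(scan[["gc", "mean_fitness", "sem_fitness"]].rename(
        columns={"sem_fitness": "sem"}))
    return scan, opt


def fixability_gap(summary_a: dict, summary_b: dict, N: int) -> float:
    """N * |difference in mean additive fitness| between two stationary states.

    Values above 1 mean the fitness advantage of one mutation bias over the
    other exceeds the drift barrier and is selectable at population size N.
    """
    la = summary_a["log_fitness"]["mean"]
    lb = summary_b["log_fitness"]["mean"]
    return N * abs(la - lb)
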
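"""Origin-fixation Monte Carlo of protein-coding genes.

In the monomorphic regime (N*mu << 1) evolution is a chain of
propose-and-fix events: a single mutant arises on the wild-type background
and either takes over the population or is lost.  For the Moran process
the fixation probability of a mutant with relative fitness r = f_mut/f_wt
in a population of N haploid individuals is

    p_fix = (1 - 1/r) / (1 - r**(-N)),   p_fix -> 1/N as r -> 1,

which the simulation uses directly as the per-proposal acceptance
probability.  Proposals follow the HKY mutation process with GC usage as
its only compositional parameter (Chargaff parity) and
transition/transversion ratio kappa; proposals that create a stop codon
are scored fitness 0 and therefore never accepted, keeping the proposal
measure exactly HKY.  Time is indexed by proposal events and trajectories
by accepted substitutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .sequences import (CODON_INDEX, CODONS, NT_INDEX, NUCLEOTIDES,
                        CodingSequence, GeneticCode, STANDARD_CODE,
                        hky_nucleotide_frequencies, translate)
from .stability import (EnergyModel, FitnessSpec, StabilityCalculator,
                        StabilityPair, fitness as fitness_fn,
                        normalized_stabilities)
from .structure import ContactMap

#: transition partners in ACGT index order: A<->G, C<->T
TRANSITION = np.array([2, 3, 0, 1])


@dataclass
class HKYModel:
    """HKY mutation process under Chargaff's second parity rule.

    The stationary base frequencies are f_G = f_C = gc/2 and
    f_A = f_T = (1-gc)/2, so GC usage is the single compositional
    parameter; transitions carry an extra factor kappa.  The microscopic
    rate scale cancels from the origin-fixation dynamics.
    """

    gc: float = 0.5
    kappa: float = 4.0
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def pi(self) -> np.ndarray:
        return hky_nucleotide_frequencies(self.gc)

    def rate_matrix(self) -> np.ndarray:
        """4x4 rate matrix Q in ACGT order; rows sum to zero."""
        pi = self.pi
        q = np.tile(pi, (4, 1)) * self.rate_scale
        for a in range(4):
            q[a, TRANSITION[a]] *= self.kappa
            q[a, a] = 0.0
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def out_rates(self) -> np.ndarray:
        """Total mutation outflow rate of each resident nucleotide."""
        q = self.rate_matrix()
        return -np.diag(q)


def hky_rate(from_nt: str | int, to_nt: str | int, hky: HKYModel) -> float:
    """Mutation rate a -> b: rate_scale * pi_b, times kappa for transitions."""
    a = NT_INDEX[from_nt] if isinstance(from_nt, str) else from_nt
    b = NT_INDEX[to_nt] if isinstance(to_nt, str) else to_nt
    if a == b:
        raise ValueError("hky_rate is defined for distinct nucleotides")
    r = hky.rate_scale * hky.pi[b]
    if TRANSITION[a] == b:
        r *= hky.kappa
    return float(r)


def propose_mutation(seq: CodingSequence, hky: HKYModel,
                     rng: np.random.Generator) -> tuple[int, str]:
    """Draw one mutation proposal (site, new nucleotide); pure, seq untouched.

    The site is drawn with probability proportional to the total outflow
    rate of its resident nucleotide, then the new nucleotide with
    probability proportional to the rate away from the resident one --
    exactly the law of mutation events under HKY.
    """
    nt = seq.nt_indices()
    out = hky.out_rates()
    w = out[nt]
    site = int(rng.choice(len(nt), p=w / w.sum()))
    q = hky.rate_matrix()
    row = q[nt[site]].clip(min=0.0)
    row[nt[site]] = 0.0
    new = int(rng.choice(4, p=row / row.sum()))
    return site, NUCLEOTIDES[new]


def moran_fixation_probability(f_wt: float, f_mut: float, N: int) -> float:
    """Fixation probability of a single mutant under the Moran process.

    Closed form (1 - 1/r)/(1 - r**(-N)) with r = f_mut/f_wt; continuous at
    r = 1 where it equals the neutral value 1/N.  Lethal mutants (f_mut = 0)
    never fix; with N = 1 every viable mutant "fixes" immediately.
    """
    if f_wt <= 0.0:
        raise ValueError("wild-type fitness must be positive")
    if N < 1:
        raise ValueError("population size must be >= 1")
    if f_mut <= 0.0:
        return 0.0
    if N == 1:
        return 1.0
    r = f_mut / f_wt
    if abs(r - 1.0) < 1e-12:
        return 1.0 / N
    e = -N * math.log(r)
    if e > 700.0:  # strongly deleterious: p underflows
        return 0.0
    p = (1.0 - 1.0 / r) / (1.0 - math.exp(e))
    return min(max(p, 0.0), 1.0)


def combined_fitness(per_protein_fitness: Sequence[float],
                     mode: Literal["min", "product"] = "min") -> float:
    """Genome fitness from per-protein fitnesses.

    ``min`` treats the least stable protein as limiting; ``product``
    assumes absence of epistatic interactions.  Every protein is
    essential: one nonviable protein zeroes the genome fitness either way.
    """
    vals = list(per_protein_fitness)
    if not vals:
        raise ValueError("empty fitness list")
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError("per-protein fitness must lie in [0, 1]")
    if mode == "min":
        return min(vals)
    if mode == "product":
        return float(np.prod(vals))
    raise ValueError(f"unknown combination mode {mode!r}")


@dataclass
class EvolutionRun:
    """Parameters of one origin-fixation run.

    Burn-in and collection are counted in accepted substitutions; replicas
    differ only by seed (replica r uses seed + r).  The monomorphic-limit
    premise N*mu << 1 is a modeling assumption, not enforced numerically.
    """

    N: int
    hky: HKYModel = field(default_factory=HKYModel)
    fitness_spec: FitnessSpec = field(default_factory=FitnessSpec)
    n_accept_total: int = 2000
    burn_in: int | None = None  # default: 5 * L_aa, set at run time
    replicas: int = 10
    seed: int = 0
    max_proposals: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("population size must be >= 1")
        if self.burn_in is not None and self.burn_in >= self.n_accept_total:
            raise ValueError("burn_in must be smaller than n_accept_total")

    def resolved_burn_in(self, L_aa: int) -> int:
        if self.burn_in is not None:
            return self.burn_in
        return min(5 * L_aa, self.n_accept_total // 2)

    def resolved_max_proposals(self) -> int:
        if self.max_proposals is not None:
            return self.max_proposals
        return 1000 * self.N * self.n_accept_total + 1_000_000


SUMMARY_FIELDS = ("fitness", "log_fitness", "dG_unf", "alpha_gap", "x", "y", "gc3")


@dataclass
class EvolveResult:
    trajectory: pd.DataFrame
    summary: dict

    def mean(self, field_: str) -> float:
        return self.summary[field_]["mean"]

    def sem(self, field_: str) -> float:
        return self.summary[field_]["sem"]


class _GeneState:
    """Mutable per-gene state of the engine."""

    __slots__ = ("nt", "calc", "aa_of_codon", "fitness", "x", "y", "sp", "fs",
                 "n_nt", "gc3_count")

    def __init__(self, gene: CodingSequence, cmap: ContactMap,
                 model: EnergyModel, fs: FitnessSpec):
        prot = translate(gene)  # raises NonviableSequenceError on stops
        if len(prot) != cmap.L:
            raise ValueError("translated gene length != contact-map size")
        self.nt = gene.nt_indices()
        self.n_nt = len(self.nt)
        self.calc = StabilityCalculator(prot, cmap, model)
        self.aa_of_codon = gene.code.aa_lookup()
        self.fs = fs
        self.sp = self.calc.current()
        self.x, self.y = normalized_stabilities(self.sp, fs)
        self.fitness = fitness_fn(self.x, self.y, fs)
        self.gc3_count = int(np.isin(self.nt[2::3], (1, 2)).sum())

    def codon_index(self, codon: int) -> int:
        b = 3 * codon
        return int(16 * self.nt[b] + 4 * self.nt[b + 1] + self.nt[b + 2])


def _summarize(traj: pd.DataFrame, burn_in: int, replicas: int) -> dict:
    """Means with replica-level SEMs over post-burn-in accepted states."""
    post = traj[traj["accept_idx"] >= burn_in]
    summary: dict = {"n_records": int(len(post))}
    for f in SUMMARY_FIELDS:
        rep_means = post.groupby("replica")[f].mean()
        mean = float(rep_means.mean())
        sem = float(rep_means.std(ddof=1) / math.sqrt(len(rep_means))) if len(rep_means) > 1 else float("nan")
        summary[f] = {"mean": mean, "sem": sem,
                      "replica_means": [float(v) for v in rep_means]}
    return summary


def _run_engine(genes: Sequence[tuple[CodingSequence, ContactMap]],
                model: EnergyModel, run: EvolutionRun,
                mode: Literal["min", "product"] = "min",
                fitness_specs: Sequence[FitnessSpec] | None = None) -> EvolveResult:
    from bisect import bisect_right

    if not genes:
        raise ValueError("need at least one gene")
    if fitness_specs is None:
        fitness_specs = [run.fitness_spec] * len(genes)
    L_aa_total = sum(c.L for _, c in genes)
    burn_in = run.resolved_burn_in(L_aa_total)
    max_props = run.resolved_max_proposals()
    N = run.N
    out = run.hky.out_rates()
    q = run.hky.rate_matrix().clip(min=0.0)
    np.fill_diagonal(q, 0.0)
    cond_cum = [list(row) for row in np.cumsum(q / q.sum(axis=1, keepdims=True), axis=1)]
    gene_len = np.array([len(g.nucleotides) for g, _ in genes], dtype=float)
    gene_cum = list(np.cumsum(gene_len / gene_len.sum()))
    n_genes = len(genes)
    _off = (16, 4, 1)
    sqrt, log_ = math.sqrt, math.log

    records: list[tuple] = []
    for rep in range(run.replicas):
        rng = np.random.default_rng(run.seed + rep)
        states = [_GeneState(g, c, model, fs)
                  for (g, c), fs in zip(genes, fitness_specs)]
        for st in states:
            if st.fitness <= 0.0:
                raise ValueError("initial sequence is nonviable (fitness 0)")
        fits = [st.fitness for st in states]
        f_wt = combined_fitness(fits, mode)
        n_third = sum(st.n_nt for st in states) // 3
        gc3_count = sum(st.gc3_count for st in states)
        # hot-loop caches: plain python lists for scalar access speed
        nts = [list(st.nt) for st in states]
        aa_ofs = [list(st.aa_of_codon) for st in states]
        site_cum = [list(np.cumsum(out[st.nt])) for st in states]
        CU = [st.calc.contactU.tolist() for st in states]
        RU = [st.calc.rowU.tolist() for st in states]
        RU2 = [st.calc.rowU2.tolist() for st in states]
        # per-gene stability constants
        inv_np = [1.0 / st.calc.n_pairs for st in states]
        nc = [float(c.n_contacts) for _, c in genes]
        rem_scale = [sqrt(2.0 * c.n_contacts * model.omega * c.L) for _, c in genes]
        sL = [model.s_conf * c.L for _, c in genes]
        inv_dgthr = [1.0 / fs.dG_threshold for fs in fitness_specs]
        inv_althr = [1.0 / fs.alpha_threshold for fs in fitness_specs]
        gap_by_rem = model.gap_normalizer == "rem"
        n_accept = 0
        proposal = 0
        inv_N = 1.0 / N
        # pre-drawn uniforms, refilled in blocks
        ublock = rng.random(1 << 14)
        ui = 0
        un = len(ublock)
        while n_accept < run.n_accept_total:
            proposal += 1
            if proposal > max_props:
                raise RuntimeError(
                    f"watchdog: {max_props} proposals without reaching "
                    f"{run.n_accept_total} accepted substitutions")
            if ui + 4 > un:
                ublock = rng.random(1 << 14)
                ui = 0
            if n_genes > 1:
                g = bisect_right(gene_cum, ublock[ui]); ui += 1
            else:
                g = 0
            st = states[g]
            sc = site_cum[g]
            nt = nts[g]
            aa_of = aa_ofs[g]
            site = bisect_right(sc, ublock[ui] * sc[-1]); ui += 1
            a = nt[site]
            b = bisect_right(cond_cum[a], ublock[ui]); ui += 1
            codon = site // 3
            base = 3 * codon
            c_old = 16 * nt[base] + 4 * nt[base + 1] + nt[base + 2]
            c_new = c_old + (b - a) * _off[site - base]
            aa_new = aa_of[c_new]
            if aa_new < 0:
                continue  # stop codon: fitness 0, never accepted
            aa_old = aa_of[c_old]
            if aa_new == aa_old:
                # synonymous: r = 1, neutral fixation probability
                p = inv_N
                sp_new, x_new, y_new, f_new = st.sp, st.x, st.y, st.fitness
            else:
                # inline single-substitution stability update
                cu_row = CU[g][codon]
                ru_row = RU[g][codon]
                ru2_row = RU2[g][codon]
                e = st.calc.E_nat + cu_row[aa_new] - cu_row[aa_old]
                s1 = st.calc.S1 + ru_row[aa_new] - ru_row[aa_old]
                s2 = st.calc.S2 + ru2_row[aa_new] - ru2_row[aa_old]
                ubar = s1 * inv_np[g]
                var = s2 * inv_np[g] - ubar * ubar
                e_rem = nc[g] * ubar - (sqrt(var) if var > 0 else 0.0) * rem_scale[g]
                dg = -(e + sL[g])
                denom = abs(e_rem) if gap_by_rem else abs(e)
                alpha = (e_rem - e) / denom if denom > 1e-12 else float("nan")
                x_new = dg * inv_dgthr[g]
                y_new = alpha * inv_althr[g]
                f_new = fitness_fn(x_new, y_new, st.fs)
                if f_new <= 0.0:
                    continue
                if n_genes > 1:
                    new_fits = fits.copy()
                    new_fits[g] = f_new
                    f_mut_tot = combined_fitness(new_fits, mode)
                else:
                    f_mut_tot = f_new
                r = f_mut_tot / f_wt
                if -1e-12 < r - 1.0 < 1e-12:
                    p = inv_N
                else:
                    e_ = -N * log_(r)
                    p = 0.0 if e_ > 700.0 else (1.0 - 1.0 / r) / (1.0 - math.exp(e_))
                if p <= 0.0:
                    continue
                sp_new = StabilityPair(dG_unf=dg, alpha_gap=alpha)
            u = ublock[ui]; ui += 1
            if u >= p:
                continue
            # --- accept ---
            if site - base == 2:
                gc3_count += int(b == 1 or b == 2) - int(a == 1 or a == 2)
            nt[site] = b
            st.nt[site] = b
            site_cum[g] = list(np.cumsum(out[st.nt]))
            if aa_new != aa_old:
                st.calc.commit(codon, int(aa_new))
                CU[g] = st.calc.contactU.tolist()
                RU[g] = st.calc.rowU.tolist()
                RU2[g] = st.calc.rowU2.tolist()
                st.sp, st.x, st.y, st.fitness = sp_new, x_new, y_new, f_new
                fits[g] = f_new
                f_wt = combined_fitness(fits, mode)
            records.append((rep, n_accept, proposal, g, site, b,
                            st.sp.dG_unf, st.sp.alpha_gap, st.x, st.y,
                            f_wt, math.log(f_wt), gc3_count / n_third))
            n_accept += 1

    traj = pd.DataFrame.from_records(
        records,
        columns=["replica", "accept_idx", "proposal", "gene", "site", "new_nt",
                 "dG_unf", "alpha_gap", "x", "y", "fitness", "log_fitness",
                 "gc3"])
    summary = _summarize(traj, burn_in, run.replicas)
    summary["params"] = {
        "N": N, "gc": run.hky.gc, "kappa": run.hky.kappa,
        "n_accept_total": run.n_accept_total, "burn_in": burn_in,
        "replicas": run.replicas, "seed": run.seed, "mode": mode,
        "fitness": fitness_specs[0].to_dict(),
    }
    return EvolveResult(trajectory=traj, summary=summary)


def evolve(gene: CodingSequence, cmap: ContactMap, model: EnergyModel,
           run: EvolutionRun) -> EvolveResult:
    """Evolve a single gene to stationarity under mutation, selection, drift.

    Repeats propose -> translate -> stability -> fitness -> accept with the
    Moran fixation probability until ``run.n_accept_total`` substitutions
    are accepted, for each replica; records every accepted state and
    returns per-quantity means with replica-level standard errors over the
    post-burn-in trajectory.
    """
    return _run_engine([(gene, cmap)], model, run)


def evolve_genome(genes: Sequence[tuple[CodingSequence, ContactMap]],
                  model: EnergyModel, run: EvolutionRun,
                  mode: Literal["min", "product"] = "min",
                  fitness_specs: Sequence[FitnessSpec] | None = None) -> EvolveResult:
    """Evolve a multi-gene genome; at most one gene mutates per step.

    Each proposal first selects a gene with probability proportional to its
    nucleotide length, then a site within it under the HKY law; acceptance
    uses the combined fitness of the whole genome (min or product over
    proteins).  With a single gene this reduces exactly to :func:`evolve`.
    """
    return _run_engine(genes, model, run, mode=mode, fitness_specs=fitness_specs)
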
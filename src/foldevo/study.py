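"""The package's standard synthetic study system.

A fixed 30-residue compact lattice structure with the synthetic
hydrophobic contact potential, a designed reference sequence standing in
for a PDB native, and a Hill-form fitness with neutrality exponent 3 and
threshold coefficients (c_dG, c_alpha) = (0.5, 0.95).  These conditions
were chosen once so that every qualitative premise of the model holds in
the toy: under mutation alone the unfolding stability is positive only at
small GC usage while the energy gap is negative everywhere and improves
with GC; under selection the two stabilities respond oppositely to the
mutation bias; and the misfolding margin is the selectively binding
coordinate at moderate population sizes.  Tests and the acceptance
analyses all run on this one system so results are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequences import CodingSequence, reverse_translate
from .stability import (EnergyModel, FitnessSpec, StabilityPair,
                        compute_stabilities, design_reference_sequence,
                        toy_hydrophobic_model)
from .structure import ContactMap, synthetic_contact_map

#: structural seed of the standard system (identifies the structure, like a
#: PDB id; run-level randomness is seeded separately).
MAP_SEED = 1
DESIGN_SEED = 0
L_RESIDUES = 30
BETA = 3.0
C_DG = 0.5
C_ALPHA = 0.95
FITNESS_FORM = "hill"


@dataclass
class StudySystem:
    """Bundle of the structure, energetics, reference and fitness spec."""

    cmap: ContactMap
    model: EnergyModel
    reference: str
    ref_stabilities: StabilityPair
    fitness_spec: FitnessSpec
    gene: CodingSequence  # reference back-translated (the starting genotype)


def make_study_system(L: int = L_RESIDUES, map_seed: int = MAP_SEED,
                      design_seed: int = DESIGN_SEED, beta: float = BETA,
                      c_dG: float = C_DG, c_alpha: float = C_ALPHA,
                      form: str = FITNESS_FORM) -> StudySystem:
    """Build the standard synthetic study system (deterministic)."""
    cmap = synthetic_contact_map(L, seed=map_seed)
    model = toy_hydrophobic_model()
    ref = design_reference_sequence(cmap, model, seed=design_seed)
    sp = compute_stabilities(ref, cmap, model)
    fs = FitnessSpec.from_reference(sp, beta=beta, c_dG=c_dG,
                                    c_alpha=c_alpha, form=form)
    gene = reverse_translate(ref)
    return StudySystem(cmap=cmap, model=model, reference=ref,
                       ref_stabilities=sp, fitness_spec=fs, gene=gene)


def make_toy_dimer():
    """A 2-codon, 1-contact toy whose sequence space is fully enumerable.

    The single eligible pair makes the REM gap degenerate (identically 0),
    so the fitness ignores the gap coordinate (``use_gap=False``) and
    depends on the unfolding stability alone.  Used by the exact
    stationary-distribution oracle.
    """
    import numpy as np

    cmap = ContactMap(L=2, pairs=np.array([[0, 1]]), min_separation=1,
                      source="toy:dimer")
    model = toy_hydrophobic_model()
    gene = CodingSequence("ATTATC")  # Ile-Ile: a stably folded dimer
    fs = FitnessSpec(beta=2.0, c_dG=0.9, dG_ref=0.5, use_gap=False,
                     form="hill")
    return gene, cmap, model, fs
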
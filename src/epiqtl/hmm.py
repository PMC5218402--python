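"""Hidden Markov model for line-of-origin posteriors in an F2 cross.

Each F2 chromosome pair consists of one maternally and one paternally
inherited haplotype, each a mosaic of segments descending from the E or W
founder line. The hidden state at a position is the ordered pair
(origin of maternal haplotype, origin of paternal haplotype) in {E, W}^2.
Transitions along the chromosome are independent for the two haplotypes,
with switch probability given by the Haldane recombination fraction on the
female map (maternal haplotype) or male map (paternal haplotype).

Markers are microsatellite-style and only partially informative: the model
emits the observed unordered F2 allele pair given the phased alleles of the
two F1 parents. Where an F1 parent's phase at a marker cannot be resolved
from its F0 parents, the emission averages over the consistent phase
configurations (exact marginalization rather than dropping the marker).
Missing genotypes emit 1 for every state. Forward-backward uses per-step
scaling, so posteriors are accurate to well below 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import LineOriginGrid
from .maps import LinkageMap, haldane_recombination

__all__ = ["MendelianError", "PhasedF1", "phase_f1", "line_origin_posteriors",
           "grid_positions"]

# state order: (maternal origin, paternal origin)
STATES = (("E", "E"), ("E", "W"), ("W", "E"), ("W", "W"))
F2_PRIOR = np.full(4, 0.25)


class MendelianError(ValueError):
    """Observed genotype incompatible with the pedigree."""


@dataclass
class PhasedF1:
    """Phase assignments for one F1 individual.

    ``assignments[marker]`` is a tuple of (allele_from_E, allele_from_W)
    pairs consistent with the F0 parents; length 1 means resolved, length
    > 1 unresolved, absent marker means no information (parent or
    grandparents untyped there).
    """

    individual: object
    assignments: dict = field(default_factory=dict)

    def resolved(self, marker) -> bool:
        return len(self.assignments.get(marker, ())) == 1


def phase_f1(f1_id, f1_genotypes: dict, e_parent: dict, w_parent: dict) -> PhasedF1:
    """Assign each F1 allele to its E-line or W-line F0 parent.

    Parameters are per-marker genotype dicts mapping marker -> (a1, a2) or
    None for missing. An F1 allele carried by neither parent raises
    :class:`MendelianError`.
    """
    phased = PhasedF1(f1_id)
    for marker, geno in f1_genotypes.items():
        if geno is None:
            continue
        eg = e_parent.get(marker)
        wg = w_parent.get(marker)
        if eg is None or wg is None:
            continue
        x, y = geno
        candidates = []
        for aE, aW in ((x, y), (y, x)):
            if aE in eg and aW in wg and (aE, aW) not in candidates:
                candidates.append((aE, aW))
        if not candidates:
            raise MendelianError(
                f"F1 {f1_id} carries alleles {geno} at {marker} not explained "
                f"by parents {eg} / {wg}"
            )
        phased.assignments[marker] = tuple(candidates)
    return phased


def grid_positions(last_pos: float, step: float = 1.0) -> np.ndarray:
    """1 cM (by default) grid anchored at 0, inclusive of the last marker
    position rounded up to a whole step."""
    end = np.ceil(last_pos / step) * step
    return np.arange(0.0, end + step / 2, step)


def _emission(obs, dam_phase: PhasedF1, sire_phase: PhasedF1, marker) -> np.ndarray:
    """P(observed unordered allele pair | state) averaged over parent phase."""
    if obs is None:
        return np.ones(4)
    dam_opts = dam_phase.assignments.get(marker)
    sire_opts = sire_phase.assignments.get(marker)
    if dam_opts is None or sire_opts is None:
        return np.ones(4)
    target = frozenset_pair(obs)
    em = np.zeros(4)
    weight = 1.0 / (len(dam_opts) * len(sire_opts))
    for dE, dW in dam_opts:
        for sE, sW in sire_opts:
            transmit = {"E": (dE, sE), "W": (dW, sW)}
            for k, (m, p) in enumerate(STATES):
                if frozenset_pair((transmit[m][0], transmit[p][1])) == target:
                    em[k] += weight
    return em


def frozenset_pair(pair):
    a, b = pair
    return (a, b) if repr(a) <= repr(b) else (b, a)


def _transition(r_mat: float, r_pat: float) -> np.ndarray:
    tm = np.array([[1 - r_mat, r_mat], [r_mat, 1 - r_mat]])
    tp = np.array([[1 - r_pat, r_pat], [r_pat, 1 - r_pat]])
    return np.kron(tm, tp)


def line_origin_posteriors(
    f2_genotypes: dict,
    dam_phase: PhasedF1,
    sire_phase: PhasedF1,
    lmap: LinkageMap,
    chromosome,
    step: float = 1.0,
    positions=None,
) -> np.ndarray:
    """Posterior line-origin genotype probabilities for one F2 individual on
    one chromosome, at the requested grid positions.

    ``f2_genotypes`` maps marker -> unordered allele pair or None. Returns an
    array of shape (n_positions, 3) ordered (p(EE), p(EW), p(WW)).
    """
    sub = lmap.chromosome(chromosome)
    marker_pos = sub["sexavg_cM"].to_numpy(float)
    markers = list(sub["marker"])
    if positions is None:
        positions = grid_positions(marker_pos[-1], step)
    positions = np.asarray(positions, dtype=float)

    # evaluation points: grid positions plus marker positions, sorted
    pts = np.concatenate([positions, marker_pos])
    kind = np.concatenate([np.full(len(positions), -1, int), np.arange(len(markers))])
    order = np.lexsort((kind, pts))  # markers after coincident grid points
    pts, kind = pts[order], kind[order]

    fpos = lmap.sex_positions(chromosome, pts, "female")
    mpos = lmap.sex_positions(chromosome, pts, "male")
    r_f = haldane_recombination(np.maximum(np.diff(fpos), 0.0))
    r_m = haldane_recombination(np.maximum(np.diff(mpos), 0.0))

    T = len(pts)
    emissions = np.ones((T, 4))
    for t in range(T):
        if kind[t] >= 0:
            mk = markers[kind[t]]
            emissions[t] = _emission(f2_genotypes.get(mk), dam_phase, sire_phase, mk)

    # scaled forward-backward
    alpha = np.empty((T, 4))
    scale = np.empty(T)
    a = F2_PRIOR * emissions[0]
    scale[0] = a.sum()
    if scale[0] == 0:
        raise MendelianError(
            f"genotype at first informative marker on chromosome {chromosome} "
            "incompatible with all line-origin states"
        )
    alpha[0] = a / scale[0]
    trans = [_transition(r_f[t], r_m[t]) for t in range(T - 1)]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans[t - 1]) * emissions[t]
        scale[t] = a.sum()
        if scale[t] == 0:
            raise MendelianError(
                f"genotype incompatible with pedigree on chromosome {chromosome}"
            )
        alpha[t] = a / scale[t]
    beta = np.empty((T, 4))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (trans[t] @ (emissions[t + 1] * beta[t + 1])) / scale[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)

    # collapse ordered states to (EE, EW, WW) at the grid positions only;
    # positions must be passed sorted ascending (grid_positions() output is)
    keep = kind == -1
    p = post[keep]
    return np.column_stack([p[:, 0], p[:, 1] + p[:, 2], p[:, 3]])


def line_origin_grid(
    f2_table: dict,
    dam_phases: dict,
    sire_phases: dict,
    parents: dict,
    lmap: LinkageMap,
    chromosome,
    step: float = 1.0,
) -> LineOriginGrid:
    """Posteriors for many F2 on one chromosome.

    ``f2_table`` maps individual -> {marker: genotype}; ``parents`` maps
    individual -> (dam id, sire id); ``dam_phases``/``sire_phases`` map F1 id
    -> PhasedF1.
    """
    sub = lmap.chromosome(chromosome)
    positions = grid_positions(sub["sexavg_cM"].to_numpy(float)[-1], step)
    inds = list(f2_table)
    probs = np.empty((len(inds), len(positions), 3))
    for i, ind in enumerate(inds):
        dam, sire = parents[ind]
        probs[i] = line_origin_posteriors(
            f2_table[ind], dam_phases[dam], sire_phases[sire],
            lmap, chromosome, step=step, positions=positions,
        )
    return LineOriginGrid(chromosome, positions, inds, probs)
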
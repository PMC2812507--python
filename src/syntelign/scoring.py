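"""Gene-pair and column scoring with phylogenetic weighting.

The match score of two genes a, b from species at patristic distance d is

    match_scale * f(d) * min(1, 2*bs(a,b) / (bs(a,a) + bs(b,b)))

with f(d) = 1/(1+d); a non-homologous or orientation-inconsistent pair scores
-mismatch * f(d).  Two profile columns are scored by a sum-of-pairs over all
cross-species pairs, divided by |species(A)| * |species(B)|; pairs with a gap
on either side contribute 0 to the sum but stay in the denominator, so columns
with missing genes score lower — closely related species are thereby penalized
more for missing homologs than remote ones.

Mismatch, gap and the minimal alignment score threshold are likewise scaled by
f(d_bar) of the mean cross-species distance of the two profiles being aligned.
"""

from __future__ import annotations

import numpy as np

from .model import EffectiveParams, Gene, GuideTree, HomologyTable, ScoringParams


def phylo_factor(d: float) -> float:
    """Distance weight f(d) = 1/(1+d): 1 at d=0, strictly decreasing."""
    if d < 0:
        raise ValueError(f"phylogenetic distance must be >= 0 (got {d})")
    return 1.0 / (1.0 + d)


def gene_pair_score(
    a: Gene,
    b: Gene,
    hom: HomologyTable,
    d: float,
    params: ScoringParams,
    orientation_consistent: bool,
) -> float:
    """Score one cross-profile gene pair (see module docstring)."""
    f = phylo_factor(d)
    if orientation_consistent and (a.gene_id, b.gene_id) in hom:
        return params.match_scale * f * hom.normalized(a.gene_id, b.gene_id)
    return -params.mismatch * f


def column_sop_score(
    colA,
    colB,
    hom: HomologyTable,
    tree: GuideTree,
    params: ScoringParams,
    relative_orientation: str = "forward",
) -> float:
    """Sum-of-pairs score of two profile columns with disjoint species sets.

    Orientation consistency of a gene pair is ``(strand_a == strand_b) XOR
    (relative_orientation == 'reverse')``, using the strands as oriented
    within each profile.
    """
    spA = colA.profile_species
    spB = colB.profile_species
    if set(spA) & set(spB):
        raise ValueError("column species sets must be disjoint")
    sign = 1 if relative_orientation == "forward" else -1
    total = 0.0
    for sa in spA:
        enta = colA.entries.get(sa)
        if enta is None:
            continue
        ga, fa = enta
        for sb in spB:
            entb = colB.entries.get(sb)
            if entb is None:
                continue
            gb, fb = entb
            consistent = (fa * fb) == sign
            total += gene_pair_score(
                ga, gb, hom, tree.distance(sa, sb), params, consistent
            )
    return total / (len(spA) * len(spB))


def effective_params(
    params: ScoringParams,
    speciesA: set[str],
    speciesB: set[str],
    tree: GuideTree,
) -> EffectiveParams:
    """Scale mismatch, gap and min_score by f(d_bar) of the mean cross distance."""
    if not speciesA or not speciesB:
        raise ValueError("species sets must be non-empty")
    if set(speciesA) & set(speciesB):
        raise ValueError("species sets must be disjoint")
    dbar = float(
        np.mean([tree.distance(a, b) for a in speciesA for b in speciesB])
    )
    f = phylo_factor(dbar)
    return EffectiveParams(
        mismatch_eff=params.mismatch * f,
        gap_eff=params.gap * f,
        min_score_eff=params.min_score * f,
        mean_distance=dbar,
        factor=f,
    )


def pair_components(profileA, profileB, hom: HomologyTable, tree: GuideTree,
                    match_scale: float):
    """Mismatch-independent score-matrix components for a profile pair.

    Returns (match_part, mispair_part): two (lenA, lenB) float arrays where

        S = (match_part - mismatch * mispair_part) / (|spA| * |spB|)

    match_part sums match_scale*f(d)*normalized_bitscore over homologous,
    orientation-consistent cross pairs; mispair_part sums f(d) over present
    cross pairs that are non-homologous or orientation-inconsistent.
    """
    N = hom.normalized_matrix()
    dummy = hom.n_indexed
    m, n = len(profileA.columns), len(profileB.columns)
    match_part = np.zeros((m, n))
    mispair_part = np.zeros((m, n))
    for sa in profileA.species:
        ia, fa = profileA.species_arrays(sa, hom)
        pres_a = fa != 0
        for sb in profileB.species:
            ib, fb = profileB.species_arrays(sb, hom)
            f = phylo_factor(tree.distance(sa, sb))
            ia_safe = np.where(ia < 0, dummy, ia)
            ib_safe = np.where(ib < 0, dummy, ib)
            sub = np.asarray(N[ia_safe][:, ib_safe].todense())
            pres = pres_a[:, None] & (fb != 0)[None, :]
            consistent = (fa[:, None] * fb[None, :]) == 1
            good = pres & consistent & (sub > 0)
            match_part += np.where(good, match_scale * f * sub, 0.0)
            mispair_part += np.where(pres & ~good, f, 0.0)
    return match_part, mispair_part


def score_matrix(profileA, profileB, hom: HomologyTable, tree: GuideTree,
                 params: ScoringParams, cache: dict | None = None) -> np.ndarray:
    """Dense column-pair SOP score matrix for two profiles.

    ``cache`` (optional, keyed by the profiles' origin keys) memoizes the
    mismatch-independent components so parameter sweeps over the same profile
    pair only pay the assembly cost once.
    """
    key = None
    comps = None
    if cache is not None:
        key = (profileA.cache_key(), profileB.cache_key(), params.match_scale)
        comps = cache.get(key)
    if comps is None:
        comps = pair_components(profileA, profileB, hom, tree, params.match_scale)
        if cache is not None:
            cache[key] = comps
    match_part, mispair_part = comps
    denom = len(profileA.species) * len(profileB.species)
    return (match_part - params.mismatch * mispair_part) / denom
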
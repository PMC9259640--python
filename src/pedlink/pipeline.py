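"""High-level per-family linkage scan: all statistics in one engine pass.

The exact engine's forward-backward sweep is the expensive step, so the
scan evaluates both NPL statistics and the parametric LOD for every preset
trait model against the same per-locus posterior in a single pass.
"""

from __future__ import annotations

import math

import numpy as np

from .inheritance import DEFAULT_BIT_CAP, ExactEngine
from .npl import ROBDOM_VARIANT, ScoreTrack, null_moments, scores_by_state
from .parametric import (
    TraitModelContext,
    trait_likelihood_by_state,
    trait_likelihood_unlinked,
)
from .penetrance import PenetranceModel, default_models
from .pedigree import MarkerGenotypes, MarkerPanel, Pedigree


def linkage_scan(
    ped: Pedigree,
    genotypes: MarkerGenotypes,
    panel: MarkerPanel,
    models: dict[str, PenetranceModel] | None = None,
    npl_scores: tuple[str, ...] = ("pairs", "robdom"),
    engine: ExactEngine | None = None,
    bit_cap: int = DEFAULT_BIT_CAP,
) -> dict[str, ScoreTrack]:
    """NPL (Spairs, Srobdom) and parametric LOD tracks for one pedigree.

    Returns a dict keyed ``NPL_pairs``, ``NPL_robdom`` and
    ``LOD_<model-name>`` for each preset model.  All expectations are taken
    against the same exact multipoint posterior.
    """
    if models is None:
        models = default_models()
    eng = engine or ExactEngine(ped, genotypes, panel, bit_cap=bit_cap)
    arrays: dict[str, np.ndarray] = {}
    moments: dict[str, tuple[float, float]] = {}
    for kind in npl_scores:
        arrays[f"npl_{kind}"] = scores_by_state(ped, kind)
        moments[kind] = null_moments(kind, ped, bit_cap=bit_cap)
    baselines: dict[str, float] = {}
    for name, model in models.items():
        ctx = TraitModelContext.from_model(model, ped)
        baselines[name] = trait_likelihood_unlinked(ped, ctx)
        arrays[f"lod_{name}"] = trait_likelihood_by_state(ped, ctx,
                                                          bit_cap=bit_cap)
    loci, exp = eng.expectation_track(arrays)
    chroms = [panel[l].chromosome for l in loci]
    bp = np.array([panel[l].bp for l in loci])
    cms = np.array([panel[l].cM for l in loci])
    out: dict[str, ScoreTrack] = {}
    for kind in npl_scores:
        mu, sd = moments[kind]
        meta = {"score": kind, "method": "exact",
                "null_mean": mu, "null_sd": sd}
        if kind == "robdom":
            meta["robdom_variant"] = ROBDOM_VARIANT
        out[f"NPL_{kind}"] = ScoreTrack(
            chromosomes=chroms, bp=bp, cM=cms,
            values=(exp[f"npl_{kind}"] - mu) / sd,
            kind=f"NPL_{kind}", pedigree=ped.name, meta=meta)
    for name in models:
        out[f"LOD_{name}"] = ScoreTrack(
            chromosomes=chroms, bp=bp, cM=cms,
            values=np.log10(exp[f"lod_{name}"] / baselines[name]),
            kind="LOD_parametric", pedigree=ped.name,
            meta={"model": name,
                  "baseline_log10": math.log10(baselines[name])})
    return out


def peak_in_segment(
    track: ScoreTrack, chromosome: str, seg_lo_cM: float, seg_hi_cM: float,
    tol: float = 1e-9,
) -> bool:
    """Is the track's global maximum attained inside a chromosome segment?

    Within one family the sharing statistic is constant across the true
    IBD segment, so ties between the segment and elsewhere count as the
    peak being attained in the segment.
    """
    inside = [
        v for c, cm, v in zip(track.chromosomes, track.cM, track.values)
        if c == chromosome and seg_lo_cM <= cm <= seg_hi_cM
    ]
    if not inside:
        return False
    return max(inside) >= float(np.max(track.values)) - tol
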
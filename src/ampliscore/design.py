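"""Design-task orchestration: pair scoring, ranking and cross-dimer checks.

The engine never fails a design on hard thresholds.  Every candidate pair in
a legal orientation and distance is scored -- five relation features
(Tmdiff, Lendiff, Pos, Dis, oEff) each through its piecewise logistic model,
combined with both single-primer scores by the pair weight table -- and the
ranked list is always returned, however poor the best score.  The only empty
result is a template that admits no geometrically legal pair at all, which
is reported as a structured warning.

Supported tasks: generic (face-to-face on a region), genotyping and ARMS
(face-to-face around a target spot; ARMS puts the primer 3'-terminal base on
the variant, one primer per allele), inverse (back-to-back), anchored
(unidirectional, nested distance may be negative), full_covered (tile a
template into windows, top pair per window) and evaluate (score pre-designed
primers with the design-time machinery).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

from .candidate import (FeatureSet, IUPAC_TO_BASES, PrimerCandidate,
                        TemplateRegion, extract_features, score_primer,
                        walk_candidates)
from .score_model import (DEFAULT_PAIR_WEIGHTS, DEFAULT_RELATION_WEIGHTS,
                          FeatureWeights, ModelParams, default_models,
                          piecewise_score)
from .specificity import (EFFICIENCY_CUTOFF, BindingSite, Product, SeedIndex,
                          bdis_model, enumerate_products, find_binding_sites,
                          product_geometry)
from .thermo import NearestNeighborModel

logger = logging.getLogger(__name__)

TASKS = ("generic", "genotyping", "arms", "inverse", "anchored",
         "full_covered", "evaluate")

_TASK_ORIENTATION = {
    "generic": "face-to-face",
    "genotyping": "face-to-face",
    "arms": "face-to-face",
    "inverse": "back-to-back",
    "anchored": "unidirectional",
    "full_covered": "face-to-face",
    "evaluate": "face-to-face",
}


class DesignError(ValueError):
    """Invalid task configuration or inputs."""


@dataclass(frozen=True)
class DesignTask:
    """A fully resolved design task."""

    task: str = "generic"
    orientation: str = "face-to-face"
    dis_params: ModelParams = ModelParams(120, 160, 100, 180, 80, 200)
    pos_params: ModelParams = ModelParams(10, 20, 5, 45, 5, 45)
    opt_tm: float = 60.0
    n_return: int = 3
    tiling_count: int | None = None
    tiling_spacing: int | None = None
    min_len: int = 18
    max_len: int = 30
    pos_step: int = 1
    len_step: int = 2
    efficiency_cutoff: float = EFFICIENCY_CUTOFF
    max_pcr_size: int = 2000
    # product accounting per primer uses its most efficient sites; on
    # pathological repeats a primer can bind hundreds of loci, but the
    # off-target score model already saturates far below the truncated
    # tail's contribution
    max_sites_per_primer: int = 30

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise DesignError(
                f"unknown task {self.task!r}; valid: {TASKS}")
        if self.orientation != _TASK_ORIENTATION[self.task]:
            raise DesignError(
                f"task {self.task!r} requires orientation "
                f"{_TASK_ORIENTATION[self.task]!r}, got {self.orientation!r}")
        if self.n_return < 1:
            raise DesignError("n_return must be >= 1")


@dataclass(frozen=True)
class PairRelation:
    """The five relation features of a candidate pair."""

    tmdiff: float
    lendiff: int
    pos: float | None
    dis: int
    oeff: float

    def __post_init__(self) -> None:
        if self.tmdiff < 0 or self.lendiff < 0:
            raise DesignError("tmdiff and lendiff are absolute differences")


@dataclass(frozen=True)
class PairResult:
    """A scored, ranked primer pair."""

    primer1: PrimerCandidate
    primer2: PrimerCandidate
    relation: PairRelation
    score1: float
    score2: float
    relation_score: float
    final_score: float
    products: tuple[Product, ...]
    rank: int = 0
    breakdown1: Mapping[str, float] = field(default_factory=dict,
                                            compare=False)
    breakdown2: Mapping[str, float] = field(default_factory=dict,
                                            compare=False)
    relation_breakdown: Mapping[str, float] = field(default_factory=dict,
                                                    compare=False)


@dataclass(frozen=True)
class DimerHit:
    """A cross-dimer above the reporting threshold."""

    primer_a: str
    primer_b: str
    duplex_tm: float
    end_anchored: bool


@dataclass(frozen=True)
class DimerReport:
    hits: tuple[DimerHit, ...]
    n_comparisons: int
    threshold_tm: float


def relation_score(
    rel: PairRelation,
    models: Mapping[str, ModelParams] | None = None,
    weights: FeatureWeights | None = None,
    dis_params: ModelParams | None = None,
    pos_params: ModelParams | None = None,
) -> tuple[float, dict[str, float]]:
    """Weighted 0-100 score of the five relation features.

    ``rel.pos is None`` marks a task without a target spot (generic,
    full-coverage): the Pos feature is skipped and its weight redistributed
    proportionally over the remaining features.
    """
    if models is None:
        models = default_models()
    if weights is None:
        weights = DEFAULT_RELATION_WEIGHTS
    scores = {
        "Tmdiff": piecewise_score(rel.tmdiff, models["Tmdiff"]),
        "Lendiff": piecewise_score(rel.lendiff, models["Lendiff"]),
        "Dis": piecewise_score(rel.dis, dis_params or models["Dis"]),
        "oEff": piecewise_score(rel.oeff, models["oEff"]),
    }
    if rel.pos is None:
        weights = weights.drop("Pos")
    else:
        scores["Pos"] = piecewise_score(rel.pos, pos_params or models["Pos"])
    total = sum(w * scores[name] for name, w in weights.items())
    return total, scores


def compose_pair_score(score1: float, score2: float, rel_score: float,
                       weights: FeatureWeights | None = None) -> float:
    """Final pair score: weighted mean of the three 0-100 components."""
    if weights is None:
        weights = DEFAULT_PAIR_WEIGHTS
    return (weights["Primer1"] * score1 + weights["Primer2"] * score2
            + weights["relation"] * rel_score) / 100.0


def _pair_products(
    sites1: Sequence[BindingSite],
    sites2: Sequence[BindingSite],
    task: DesignTask,
    dmodel,
) -> tuple[tuple[Product, ...], dict[tuple, float], float]:
    """Every product of the pair: cross products plus the self-products of
    each primer alone, deduplicated by geometry.

    Returns the (unflagged) products, a locus-pair -> efficiency map and
    the total efficiency sum.  Products depend only on the two sequences'
    site lists, so callers can cache this per sequence pair and derive
    each candidate pair's oEff as total - its own target contribution.
    """
    kwargs = dict(orientation=task.orientation, dis_params=task.dis_params,
                  efficiency_cutoff=task.efficiency_cutoff,
                  distance_model=dmodel)
    seen: dict[tuple, Product] = {}
    for prods in (
        enumerate_products(sites1, sites2, **kwargs),
        enumerate_products(sites1, sites1, **kwargs),
        enumerate_products(sites2, sites2, **kwargs),
    ):
        for p in prods:
            seen.setdefault((p.site1.locus, p.site2.locus), p)
    products = tuple(seen.values())
    eff_map = {key: p.efficiency for key, p in seen.items()}
    return products, eff_map, sum(eff_map.values())


def _tie_key(pr: PairResult, dis_mid: float):
    return (-pr.final_score, pr.relation.oeff,
            abs(pr.relation.dis - dis_mid), pr.primer1.id, pr.primer2.id)


def enumerate_and_score_pairs(
    cands1: Sequence[PrimerCandidate],
    cands2: Sequence[PrimerCandidate],
    task: DesignTask,
    index: SeedIndex | None,
    thermo: NearestNeighborModel,
    models: Mapping[str, ModelParams] | None = None,
    primer_weights: FeatureWeights | None = None,
    relation_weights: FeatureWeights | None = None,
    pair_weights: FeatureWeights | None = None,
    target_pos: int | None = None,
    indel_table=None,
) -> list[PairResult]:
    """Score every orientation/distance-legal pair and rank descending.

    Single-primer features, scores and binding sites are computed once per
    distinct sequence.  ``target_pos`` enables the Pos relation feature
    (distance from primer1's 3'-terminal base to the target coordinate).
    Ties are broken by smaller oEff, then distance closest to the optimal
    midpoint, then primer ids.  The list is ALWAYS the best pairs found;
    an empty list means no geometrically legal pair exists.
    """
    models = default_models(task.opt_tm, overrides=models)
    feature_cache: dict[str, tuple[float, dict, FeatureSet]] = {}
    site_cache: dict[str, list[BindingSite]] = {}

    def evaluate(cand: PrimerCandidate):
        key = cand.seq + "|" + cand.degenerate_seq
        if key not in feature_cache:
            feats = extract_features(cand, thermo, indel_table)
            total, breakdown = score_primer(feats, models, primer_weights)
            feature_cache[key] = (total, breakdown, feats)
        return feature_cache[key]

    def sites_of(cand: PrimerCandidate) -> list[BindingSite]:
        if cand.seq not in site_cache:
            if index is None:
                # no specificity reference: the intended locus only
                tm = thermo.oligo_tm(cand.seq)
                from .specificity import bound_efficiency
                site_cache[cand.seq] = [BindingSite(
                    ref_id=cand.ref_id, strand=cand.strand,
                    start=cand.start, end=cand.end, bound_tm=tm,
                    mismatch_dist3=(),
                    efficiency=bound_efficiency(tm, (), models))]
            else:
                sites = find_binding_sites(
                    cand.seq, index, thermo, models,
                    efficiency_cutoff=task.efficiency_cutoff)
                if len(sites) > task.max_sites_per_primer:
                    sites = sorted(
                        sites, key=lambda s: (-s.efficiency, s.ref_id,
                                              s.start, s.strand),
                    )[:task.max_sites_per_primer]
                    sites.sort(key=lambda s: (s.ref_id, s.start, s.strand))
                site_cache[cand.seq] = sites
        return site_cache[cand.seq]

    dmodel = bdis_model(task.dis_params, task.orientation, task.max_pcr_size)
    product_cache: dict[tuple[str, str], tuple] = {}

    def products_of(c1: PrimerCandidate, c2: PrimerCandidate):
        key = (c1.seq, c2.seq)
        if key not in product_cache:
            product_cache[key] = _pair_products(sites_of(c1), sites_of(c2),
                                                task, dmodel)
        return product_cache[key]

    site1_by_cand = [_intended_site(c) for c in cands1]
    site2_by_cand = [_intended_site(c) for c in cands2]
    dis_mid = (task.dis_params.opt_min + task.dis_params.opt_max) / 2.0
    rel_weights_active = relation_weights or DEFAULT_RELATION_WEIGHTS
    if target_pos is None:
        rel_weights_active = rel_weights_active.drop("Pos")
    results: list[PairResult] = []
    for c1, site1 in zip(cands1, site1_by_cand):
        for c2, site2 in zip(cands2, site2_by_cand):
            bdis = product_geometry(site1, site2, task.orientation)
            if bdis is None or not (task.dis_params.lim_min <= bdis
                                    <= task.dis_params.lim_max):
                continue
            pos_val: float | None = None
            if target_pos is not None:
                pos_val = abs(c1.three_prime_pos - target_pos)
                if not (task.pos_params.lim_min <= pos_val
                        <= task.pos_params.lim_max):
                    continue
            s1, b1, f1 = evaluate(c1)
            s2, b2, f2 = evaluate(c2)
            products, eff_map, eff_total = products_of(c1, c2)
            target_eff = eff_map.get((c1.locus, c2.locus), 0.0)
            rel = PairRelation(
                tmdiff=abs(f1.tm - f2.tm),
                lendiff=abs(len(c1) - len(c2)),
                pos=pos_val, dis=bdis,
                oeff=max(eff_total - target_eff, 0.0))
            rel_total, rel_breakdown = relation_score(
                rel, models, rel_weights_active,
                dis_params=task.dis_params,
                pos_params=task.pos_params if target_pos is not None
                else None)
            final = compose_pair_score(s1, s2, rel_total, pair_weights)
            results.append(PairResult(
                primer1=c1, primer2=c2, relation=rel, score1=s1,
                score2=s2, relation_score=rel_total, final_score=final,
                products=products, breakdown1=b1, breakdown2=b2,
                relation_breakdown=rel_breakdown))
    results.sort(key=lambda pr: _tie_key(pr, dis_mid))
    from dataclasses import replace as _replace
    ranked = [_replace(pr, rank=i + 1) for i, pr in enumerate(results)]
    # materialize target flags on the pairs a caller will actually report
    for i, pr in enumerate(ranked[:max(task.n_return, 10)]):
        flagged = tuple(
            _replace(p, is_target=True)
            if (p.site1.locus, p.site2.locus)
            == (pr.primer1.locus, pr.primer2.locus) else p
            for p in pr.products)
        ranked[i] = _replace(pr, products=flagged)
    if not ranked:
        logger.warning("no geometrically legal primer pair "
                       "(orientation=%s, dis=%s)", task.orientation,
                       task.dis_params.as_tuple())
    return ranked


def _intended_site(cand: PrimerCandidate) -> BindingSite:
    """The candidate's own locus viewed as a perfect binding site."""
    return BindingSite(ref_id=cand.ref_id, strand=cand.strand,
                       start=cand.start, end=cand.end, bound_tm=100.0,
                       mismatch_dist3=(), efficiency=1.0)


def full_coverage_windows(region: TemplateRegion,
                          count: int | None = None,
                          spacing: int | None = None
                          ) -> list[TemplateRegion]:
    """Equal-width half-open windows tiling a template.

    ``spacing`` (bases between window starts) converts to a window count by
    ceiling division; explicit ``count`` wins.
    """
    if count is None:
        if spacing is None:
            raise DesignError("full_covered needs tiling count or spacing")
        count = -(-len(region) // spacing)
    if count < 1:
        raise DesignError("window count must be >= 1")
    width = len(region) / count
    windows = []
    for i in range(count):
        start = region.start + round(i * width)
        end = region.start + round((i + 1) * width)
        if end > start:
            windows.append(TemplateRegion(region.ref_id, start, end))
    return windows


def _flank_region(ref_id: str, lo: int, hi: int,
                  reference: Mapping[str, str]) -> TemplateRegion | None:
    lo = max(lo, 0)
    hi = min(hi, len(reference[ref_id]))
    if hi - lo < 1:
        return None
    return TemplateRegion(ref_id, lo, hi)


def _arms_candidates(
    target: "TargetSpot",
    reference: Mapping[str, str],
    masked: Mapping[str, str] | None,
    task: DesignTask,
) -> list[PrimerCandidate]:
    """Allele-specific primers: 3'-terminal base fixed on the target, one
    candidate per allele and length, plus-strand."""
    ref_seq = reference[target.ref_id]
    alleles = target.alleles or _alleles_from_masked(masked, target)
    out = []
    for length in range(task.min_len, task.max_len + 1, task.len_step):
        start = target.pos - length + 1
        if start < 0:
            continue
        end = target.pos + 1
        context = ref_seq[start:end].upper()
        degen = (masked[target.ref_id][start:end].upper()
                 if masked else context)
        for allele in alleles:
            seq = context[:-1] + allele
            # the substituted terminal base is the assay allele, not a
            # common-SNP penalty: report it as plain sequence
            dseq = degen[:-1] + allele
            out.append(PrimerCandidate(
                id=f"arms:{target.ref_id}:{start}-{end}:+:{allele}",
                seq=seq, degenerate_seq=dseq, ref_id=target.ref_id,
                start=start, end=end, strand="+"))
    return out


def _alleles_from_masked(masked, target) -> list[str]:
    if masked is None:
        raise DesignError(
            f"ARMS target {target.ref_id}:{target.pos} has no alleles and "
            "no masked reference to read them from")
    code = masked[target.ref_id][target.pos].upper()
    bases = sorted(IUPAC_TO_BASES.get(code, frozenset()))
    if len(bases) < 2:
        raise DesignError(
            f"ARMS target {target.ref_id}:{target.pos} is not degenerate "
            f"in the masked reference ({code!r})")
    return bases


@dataclass(frozen=True)
class TargetSpot:
    """A target coordinate (0-based) with optional assay alleles."""

    ref_id: str
    pos: int
    name: str = ""
    alleles: tuple[str, ...] = ()


def design(
    task: DesignTask,
    reference: Mapping[str, str],
    regions: Sequence[TemplateRegion] | None = None,
    targets: Sequence[TargetSpot] | None = None,
    masked: Mapping[str, str] | None = None,
    specificity_index: SeedIndex | None = None,
    thermo: NearestNeighborModel | None = None,
    models: Mapping[str, ModelParams] | None = None,
    primer_weights: FeatureWeights | None = None,
    relation_weights: FeatureWeights | None = None,
    pair_weights: FeatureWeights | None = None,
    indel_table=None,
) -> dict[str, list[PairResult]]:
    """Run a design task; returns the top ``n_return`` ranked pairs per
    template region / target spot, keyed by region or target name.

    Regions or targets falling outside the reference raise; a window too
    small to hold a primer is skipped with a warning.  Fewer than
    ``n_return`` legal pairs returns as many as exist.
    """
    thermo = thermo or NearestNeighborModel()
    common = dict(task=task, index=specificity_index, thermo=thermo,
                  models=models, primer_weights=primer_weights,
                  relation_weights=relation_weights,
                  pair_weights=pair_weights, indel_table=indel_table)
    results: dict[str, list[PairResult]] = {}

    def run_region(name: str, region: TemplateRegion) -> None:
        cands1 = walk_candidates(region, reference, masked,
                                 task.min_len, task.max_len,
                                 task.pos_step, task.len_step,
                                 strands=("+",))
        cands2 = walk_candidates(region, reference, masked,
                                 task.min_len, task.max_len,
                                 task.pos_step, task.len_step,
                                 strands=("-",))
        if not cands1 or not cands2:
            logger.warning("window %s too small for a primer; skipped", name)
            results[name] = []
            return
        ranked = enumerate_and_score_pairs(cands1, cands2, **common)
        results[name] = ranked[:task.n_return]

    if task.task in ("generic", "full_covered"):
        if not regions:
            raise DesignError(f"task {task.task!r} needs template regions")
        for region in regions:
            if region.end > len(reference[region.ref_id]):
                raise DesignError(f"region {region} outside reference")
            if task.task == "generic":
                run_region(f"{region.ref_id}:{region.start}-{region.end}",
                           region)
            else:
                for w in full_coverage_windows(region, task.tiling_count,
                                               task.tiling_spacing):
                    run_region(f"{w.ref_id}:{w.start}-{w.end}", w)
        return results

    if task.task in ("genotyping", "arms", "inverse", "anchored"):
        if not targets:
            raise DesignError(f"task {task.task!r} needs target spots")
        for target in targets:
            if target.ref_id not in reference or not (
                    0 <= target.pos < len(reference[target.ref_id])):
                raise DesignError(
                    f"target {target.ref_id}:{target.pos} outside reference")
            name = target.name or f"{target.ref_id}:{target.pos}"
            results[name] = _design_target(
                task, target, reference, masked, common)
        return results

    raise DesignError(
        "the evaluate task is served by evaluate_primers(), not design()")


def _design_target(task, target, reference, masked, common):
    pos_p, dis_p = task.pos_params, task.dis_params
    max_len = task.max_len
    walk = dict(reference=reference, masked=masked, min_len=task.min_len,
                max_len=max_len, pos_step=task.pos_step,
                len_step=task.len_step)

    if task.task in ("genotyping", "arms"):
        if task.task == "arms":
            cands1 = _arms_candidates(target, reference, masked, task)
            target_pos = target.pos  # pos comes out 0 by construction
        else:
            r1 = _flank_region(target.ref_id,
                               target.pos - int(pos_p.lim_max) - max_len,
                               target.pos - int(pos_p.lim_min) + 1,
                               reference)
            cands1 = (walk_candidates(r1, strands=("+",), **walk)
                      if r1 else [])
            cands1 = [c for c in cands1 if c.three_prime_pos < target.pos]
            target_pos = target.pos
        r2 = _flank_region(target.ref_id, target.pos + 1,
                           target.pos + int(dis_p.lim_max) + 1, reference)
        cands2 = walk_candidates(r2, strands=("-",), **walk) if r2 else []
    elif task.task == "inverse":
        halo = int(pos_p.lim_max) + max_len
        r1 = _flank_region(target.ref_id, target.pos - halo,
                           target.pos + halo, reference)
        cands1 = walk_candidates(r1, strands=("-",), **walk) if r1 else []
        r2 = _flank_region(target.ref_id, target.pos,
                           target.pos + halo + int(dis_p.lim_max) + max_len,
                           reference)
        cands2 = walk_candidates(r2, strands=("+",), **walk) if r2 else []
        target_pos = target.pos
    elif task.task == "anchored":
        r1 = _flank_region(target.ref_id,
                           target.pos - int(pos_p.lim_max) - max_len,
                           target.pos - int(pos_p.lim_min) + 1, reference)
        cands1 = walk_candidates(r1, strands=("+",), **walk) if r1 else []
        cands1 = [c for c in cands1 if c.three_prime_pos < target.pos]
        r2 = _flank_region(target.ref_id,
                           target.pos - int(pos_p.lim_max) - max_len
                           + int(dis_p.lim_min),
                           target.pos + 1, reference)
        cands2 = walk_candidates(r2, strands=("+",), **walk) if r2 else []
        target_pos = target.pos
    else:  # pragma: no cover
        raise DesignError(task.task)

    if not cands1 or not cands2:
        logger.warning("no candidates around target %s:%s",
                       target.ref_id, target.pos)
        return []
    ranked = enumerate_and_score_pairs(cands1, cands2,
                                       target_pos=target_pos, **common)
    return ranked[:task.n_return]


def evaluate_primers(
    primers: Mapping[str, str],
    thermo: NearestNeighborModel | None = None,
    models: Mapping[str, ModelParams] | None = None,
    weights: FeatureWeights | None = None,
    opt_tm: float = 60.0,
    specificity_index: SeedIndex | None = None,
) -> dict[str, dict]:
    """Score pre-designed primers exactly as design-time candidates.

    IUPAC codes in the input sequence are treated as covered SNPs (the
    plain sequence resolves them to an arbitrary allele for thermodynamics).
    Returns per-primer feature values, per-feature scores, the total and,
    when a specificity index is given, the binding sites.
    """
    thermo = thermo or NearestNeighborModel()
    models = default_models(opt_tm, overrides=models)
    out: dict[str, dict] = {}
    for name, dseq in primers.items():
        dseq = dseq.upper()
        # degenerate codes resolve to the weakest-stacking allele (A/T
        # preferred) so the reported Tm is the conservative one
        plain = "".join(
            b if b in "ACGT" else
            next(x for x in "ATCG" if x in IUPAC_TO_BASES[b])
            for b in dseq)
        cand = PrimerCandidate(id=name, seq=plain, degenerate_seq=dseq,
                               ref_id=name, start=0, end=len(plain),
                               strand="+")
        feats = extract_features(cand, thermo)
        total, breakdown = score_primer(feats, models, weights)
        entry = {"features": feats, "scores": breakdown, "total": total}
        if specificity_index is not None:
            entry["sites"] = find_binding_sites(plain, specificity_index,
                                                thermo, models)
        out[name] = entry
    return out


def check_cross_dimers(
    primers: Mapping[str, str],
    thermo: NearestNeighborModel | None = None,
    threshold_tm: float = 45.0,
) -> DimerReport:
    """All-vs-all duplex screen over a primer panel, self pairs included.

    Reporting only -- no automatic re-selection; hits at or above the
    threshold carry a flag marking extensible (3'-anchored) dimers.
    """
    thermo = thermo or NearestNeighborModel()
    names = sorted(primers)
    hits = []
    n = 0
    for a, b in combinations_with_replacement(names, 2):
        n += 1
        tm, anchored = thermo.cross_dimer(primers[a], primers[b])
        if tm >= threshold_tm:
            hits.append(DimerHit(primer_a=a, primer_b=b, duplex_tm=tm,
                                 end_anchored=anchored))
    return DimerReport(hits=tuple(hits), n_comparisons=n,
                       threshold_tm=threshold_tm)


def pairs_from_selection(
    results: Mapping[str, Sequence[PairResult]],
) -> dict[str, str]:
    """Primer id -> sequence map over every selected pair, for the
    cross-dimer screen."""
    panel: dict[str, str] = {}
    for target, pairs in results.items():
        for pr in pairs:
            panel[f"{target}|{pr.rank}|1"] = pr.primer1.seq
            panel[f"{target}|{pr.rank}|2"] = pr.primer2.seq
    return panel
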
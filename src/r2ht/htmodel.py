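"""Divergence-versus-host-age analysis and horizontal-transfer inference.

Vertically inherited elements diverge in proportion to the age of their
hosts' split, so regressing pairwise element divergence on host split
age should give a positive, tight trend.  A horizontally transferred
element is *less* divergent than the host split age predicts (the copies
separated at the transfer, not at the speciation), while ancient
paralogous lineages are *more* divergent.  The analysis therefore:

1. assembles one point per cross-taxon element pair
   (split age in Myr, nucleotide divergence, amino-acid divergence),
   excluding ancient paralogs (median divergence above a cutoff) and
   degenerate copies with no meaningful reading frame;
2. fits ordinary least squares of divergence on age and reports the
   squared Pearson correlation;
3. flags pairs falling significantly *below* the trend, by iteratively
   pruning the most negative residual while it exceeds ``t_flag`` robust
   (median/MAD-scaled) standard deviations;
4. refits after exclusion — transfer candidates removed, the vertical
   signal should emerge as a much higher R²;
5. partitions elements into lineages (divergence <= 1% and identical
   large-indel profile), tests patchy distribution of each lineage on
   the host tree, collects element-versus-host topology conflicts, and
   groups candidate pairs into a minimal set of transfer events scored
   against the three classic criteria: (i) lower-than-expected
   divergence, (ii) phylogenetic incongruence, (iii) patchy
   distribution.

The public surface follows the statsmodels convention: build a
:class:`DivergenceAgeModel` from a distance matrix / mapping / host
tree, call :meth:`~DivergenceAgeModel.fit`, inspect the returned
:class:`DivergenceAgeResults` (estimates, flagged pairs, ``summary()``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distances import DistanceMatrix
from .elements import StructuralVariant
from .hosts import DatedHostTree
from .treebuild import ElementTree

DEFAULT_T_FLAG = 2.0
DEFAULT_LINEAGE_THRESHOLD = 0.01
DEFAULT_PARALOG_CUTOFF = 0.5


@dataclass(frozen=True)
class AgeDivergencePoint:
    pair: frozenset          # the two element ids
    taxa: frozenset          # their host taxa
    age: float               # host split age, Myr
    d_nt: float | None
    d_aa: float | None


@dataclass
class AgeDivergenceSet:
    points: list[AgeDivergencePoint]
    excluded_elements: dict[str, str] = field(default_factory=dict)
    include_intra_taxon: bool = False

    def frame(self, response: str = "nt") -> pd.DataFrame:
        rows = [
            {"a": min(p.pair), "b": max(p.pair), "age": p.age,
             "d": getattr(p, f"d_{response}")}
            for p in self.points
            if getattr(p, f"d_{response}") is not None
        ]
        return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    """OLS of divergence on host split age."""

    slope: float             # divergence per Myr
    intercept: float
    r2: float                # squared Pearson correlation
    pearson_r: float
    p_value: float
    n_points: int
    excluded_pairs: set[frozenset] = field(default_factory=set)

    def predict(self, age):
        return self.intercept + self.slope * np.asarray(age)


@dataclass
class LineagePartition:
    blocks: list[frozenset]
    threshold: float
    indel_profiles: dict[str, frozenset] = field(default_factory=dict)

    def block_of(self, element: str) -> frozenset:
        for b in self.blocks:
            if element in b:
                return b
        raise KeyError(element)


@dataclass
class HTEvent:
    """One reconstructed horizontal-transfer event.

    ``hub`` is the element shared by every supporting pair; its partners
    are the elements on the other side.  Direction is a tree-nesting
    heuristic, not a statistical inference: when the hub nests inside
    the partner clade it is called the recipient copy, otherwise the
    donor.  ``recipient_taxa``/``donor_taxa`` are host-taxon sets (a
    multi-taxon recipient reads as a transfer into that clade's
    ancestor).
    """

    hub: str
    partners: frozenset
    donor_taxa: frozenset
    recipient_taxa: frozenset
    supporting_pairs: set[frozenset]
    age_upper_bound_myr: float | None
    criteria: dict[str, bool]
    direction_is_heuristic: bool = True

    @property
    def taxa(self) -> frozenset:
        return self.donor_taxa | self.recipient_taxa


# ---------------------------------------------------------------------------
# point assembly and regression


def assemble_points(
    nt_matrix: DistanceMatrix,
    mapping: pd.DataFrame,
    host: DatedHostTree,
    aa_matrix: DistanceMatrix | None = None,
    include_intra_taxon: bool = False,
    include_degenerate: bool = False,
    paralog_cutoff: float = DEFAULT_PARALOG_CUTOFF,
) -> AgeDivergenceSet:
    """One (age, divergence) point per includable element pair.

    ``mapping`` needs columns ``element_id``, ``taxon`` and optionally
    ``degenerate`` (0/1).  Elements whose median nucleotide divergence
    to all others exceeds ``paralog_cutoff`` are excluded as ancient
    paralogous lineages; degenerate elements are excluded unless
    ``include_degenerate`` (they have no meaningful translation, and
    both divergence responses use one shared point set).
    """
    taxon = dict(zip(mapping["element_id"], mapping["taxon"]))
    degenerate = set(
        mapping.loc[
            mapping.get("degenerate", 0).astype(int) == 1, "element_id"
        ]
    ) if "degenerate" in mapping.columns else set()
    unmapped = [lab for lab in nt_matrix.labels if lab not in taxon]
    if unmapped:
        raise KeyError(f"elements missing from mapping: {unmapped}")
    unknown = sorted(set(taxon.values()) - set(host.taxa))
    if unknown:
        raise KeyError(f"mapping taxa not in host tree: {unknown}")

    excluded: dict[str, str] = {}
    for lab in nt_matrix.labels:
        others = [
            nt_matrix.get(lab, o) for o in nt_matrix.labels
            if o != lab and nt_matrix.is_computed(lab, o)
        ]
        if others and float(np.median(others)) > paralog_cutoff:
            excluded[lab] = "paralog"
    if not include_degenerate:
        for lab in degenerate:
            excluded.setdefault(lab, "degenerate")

    kept = [lab for lab in nt_matrix.labels if lab not in excluded]
    points = []
    for a, b in itertools.combinations(kept, 2):
        if taxon[a] == taxon[b] and not include_intra_taxon:
            continue
        d_nt = (nt_matrix.get(a, b)
                if nt_matrix.is_computed(a, b) else None)
        if d_nt is None:
            continue
        d_aa = None
        if aa_matrix is not None and a in aa_matrix.labels \
                and b in aa_matrix.labels and aa_matrix.is_computed(a, b):
            d_aa = aa_matrix.get(a, b)
            if np.isnan(d_aa):
                d_aa = None
        points.append(AgeDivergencePoint(
            pair=frozenset((a, b)),
            taxa=frozenset((taxon[a], taxon[b])),
            age=host.split_age(taxon[a], taxon[b]),
            d_nt=d_nt,
            d_aa=d_aa,
        ))
    return AgeDivergenceSet(
        points=points,
        excluded_elements=excluded,
        include_intra_taxon=include_intra_taxon,
    )


def fit_divergence_age(
    points: AgeDivergenceSet | list[AgeDivergencePoint],
    exclude: set[frozenset] | None = None,
    response: str = "nt",
) -> RegressionResult:
    """OLS of divergence on age; R² is the squared Pearson correlation."""
    pts = points.points if isinstance(points, AgeDivergenceSet) else points
    exclude = exclude or set()
    data = [
        (p.age, getattr(p, f"d_{response}"))
        for p in pts
        if p.pair not in exclude and getattr(p, f"d_{response}") is not None
    ]
    if len(data) < 3:
        raise ValueError(
            f"need >= 3 points after exclusion, got {len(data)}"
        )
    x = np.array([a for a, _ in data])
    y = np.array([d for _, d in data])
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_points=len(data),
        excluded_pairs=set(exclude),
    )


def _robust_z(resid: np.ndarray) -> np.ndarray:
    med = np.median(resid)
    mad = np.median(np.abs(resid - med))
    if mad == 0:
        return np.full_like(resid, np.nan)
    return (resid - med) / (1.4826 * mad)


def _ols_studentized(x: np.ndarray, resid: np.ndarray) -> np.ndarray:
    n = len(x)
    dof = n - 2
    if dof <= 0:
        return np.full_like(resid, np.nan)
    s2 = float(resid @ resid) / dof
    sx = np.sum((x - x.mean()) ** 2)
    h = 1.0 / n + (x - x.mean()) ** 2 / sx
    denom = np.sqrt(s2 * (1 - h))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, resid / denom, np.nan)


def flag_candidates(
    points: AgeDivergenceSet | list[AgeDivergencePoint],
    method: str = "residual",
    t_flag: float = DEFAULT_T_FLAG,
    scale: str = "mad",
    f: float = 0.5,
    response: str = "nt",
    min_points: int = 4,
    corroborate_f: float | None = 0.5,
) -> set[frozenset]:
    """Flag pairs significantly *below* the divergence-age trend.

    ``method='residual'`` (default): iteratively fit OLS on the active
    points, standardize residuals (``scale='mad'``: median/MAD robust
    sigma, which stays honest when transferred pairs contaminate the
    fit; ``scale='ols'``: classic internally studentized residuals), and
    remove the single most negative point while its score is below
    ``-t_flag``.  Removed pairs are the candidates.  Only points below
    the trend are ever flagged: transfer lowers divergence, paralogy
    raises it.  Unless ``corroborate_f`` is None, a candidate must
    additionally lie below ``corroborate_f`` times the maximum
    divergence of its own age class (classes with >= 2 points): the
    regression line alone can leave systematic lack-of-fit residuals
    (the true divergence-age curve saturates), and a transfer claim
    needs a co-eval vertical reference to stand against.

    ``method='age-class'``: flag pairs with divergence below ``f`` times
    the maximum divergence of their age class (robust to heavy
    contamination of a class, but blind in single-pair classes).
    """
    pts = points.points if isinstance(points, AgeDivergenceSet) else points
    usable = [
        p for p in pts if getattr(p, f"d_{response}") is not None
    ]
    if method == "age-class":
        flagged = set()
        by_age: dict[float, list] = {}
        for p in usable:
            by_age.setdefault(p.age, []).append(p)
        for age, group in by_age.items():
            if len(group) < 2:
                continue
            top = max(getattr(p, f"d_{response}") for p in group)
            for p in group:
                if getattr(p, f"d_{response}") < f * top:
                    flagged.add(p.pair)
        return flagged
    if method != "residual":
        raise ValueError(f"unknown flagging method {method!r}")

    active = list(usable)
    flagged: set[frozenset] = set()
    while len(active) > max(min_points, 3):
        x = np.array([p.age for p in active])
        y = np.array([getattr(p, f"d_{response}") for p in active])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        z = _robust_z(resid) if scale == "mad" \
            else _ols_studentized(x, resid)
        if np.all(np.isnan(z)):
            break
        i = int(np.nanargmin(z))
        if z[i] < -t_flag:
            flagged.add(active[i].pair)
            active.pop(i)
        else:
            break
    if corroborate_f is not None and flagged:
        by_age: dict[float, list] = {}
        for p in usable:
            by_age.setdefault(p.age, []).append(
                getattr(p, f"d_{response}")
            )
        kept = set()
        for p in usable:
            if p.pair not in flagged:
                continue
            cls = by_age[p.age]
            if len(cls) >= 2 and getattr(p, f"d_{response}") \
                    < corroborate_f * max(cls):
                kept.add(p.pair)
        flagged = kept
    return flagged


# ---------------------------------------------------------------------------
# lineages, patchiness, topology conflict, events


def assign_lineages(
    matrix: DistanceMatrix,
    indel_profiles: dict[str, set[StructuralVariant]] | None = None,
    threshold: float = DEFAULT_LINEAGE_THRESHOLD,
    elements: list[str] | None = None,
) -> LineagePartition:
    """Partition elements into lineages.

    Two elements belong to the same lineage iff their nucleotide
    divergence is <= ``threshold`` (the classic 1% rule) *and* they
    carry the identical large-indel profile — a shared large deletion
    binds copies together, an unshared one separates them even at low
    divergence.  The partition is the transitive closure over
    qualifying pairs.
    """
    labels = list(elements) if elements is not None else list(matrix.labels)
    profiles = {
        lab: frozenset(indel_profiles.get(lab, set()))
        for lab in labels
    } if indel_profiles else {lab: frozenset() for lab in labels}
    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(labels, 2):
        if not matrix.is_computed(a, b):
            continue
        if matrix.get(a, b) <= threshold and profiles[a] == profiles[b]:
            parent[find(a)] = find(b)
    blocks: dict[str, set[str]] = {}
    for lab in labels:
        blocks.setdefault(find(lab), set()).add(lab)
    return LineagePartition(
        blocks=sorted(
            (frozenset(b) for b in blocks.values()), key=sorted
        ),
        threshold=threshold,
        indel_profiles=profiles,
    )


def patchy_distribution(
    block: frozenset,
    mapping: pd.DataFrame,
    host: DatedHostTree,
) -> bool:
    """Is a lineage present-in-some / absent-in-sister on the host tree?

    True iff the lineage occupies at least two taxa whose set is *not*
    monophyletic on the host tree restricted to surveyed taxa — i.e.
    some surveyed taxon inside the lineage's host clade lacks it.
    """
    taxon = dict(zip(mapping["element_id"], mapping["taxon"]))
    hosts_of_block = {taxon[e] for e in block}
    if len(hosts_of_block) < 2:
        return False
    return not host.is_clade_among_surveyed(
        hosts_of_block & host.surveyed
    )


def topology_conflicts(
    element_tree: ElementTree,
    host: DatedHostTree,
    mapping: pd.DataFrame,
    s_min: float = 70.0,
) -> tuple[list[dict], int]:
    """Element-tree vs host-tree incongruence.

    Element-tree edges are translated to host-taxon sets through the
    mapping (several elements of one taxon may sit on both sides of an
    edge).  A host bipartition A|B conflicts with an element edge C|D
    when all four taxon-set intersections are non-empty — the
    generalization of split incompatibility to multi-labelled trees.
    Edges with bootstrap support below ``s_min`` (when supports exist)
    are ignored.  Also returns a clade-based Robinson–Foulds-style
    distance: the symmetric difference between the host tree's clades
    and the element tree's *clean* taxon clades (edges whose two sides
    share no taxon).
    """
    taxon = dict(zip(mapping["element_id"], mapping["taxon"]))
    all_elements = set(element_tree.leaf_labels())
    unmapped = sorted(all_elements - set(taxon))
    if unmapped:
        raise KeyError(f"elements missing from mapping: {unmapped}")

    conflicts = []
    clean_clades: set[frozenset] = set()
    for side in element_tree.clades():
        sup = element_tree.support.get(
            _canon_side(side, element_tree.leaf_labels())
        )
        other = all_elements - side
        taxa_c = frozenset(taxon[e] for e in side)
        taxa_d = frozenset(taxon[e] for e in other)
        if not (taxa_c & taxa_d):
            clean_clades.add(taxa_c)
        if sup is not None and sup < s_min:
            continue
        for clade_a, comp_b in host.bipartitions():
            if (taxa_c & clade_a and taxa_c & comp_b
                    and taxa_d & clade_a and taxa_d & comp_b):
                key = (frozenset(clade_a), taxa_c)
                if any((c["host_clade"], c["element_side_taxa"]) == key
                       for c in conflicts):
                    continue
                conflicts.append({
                    "host_clade": frozenset(clade_a),
                    "element_side_taxa": taxa_c,
                    "support": sup,
                })
    host_clades = {
        frozenset(a) for a, _ in host.bipartitions()
    }
    rf = len(host_clades ^ clean_clades)
    return conflicts, rf


def _canon_side(side: frozenset, labels: list[str]) -> frozenset:
    first = min(labels)
    if first in side:
        return frozenset(set(labels) - side)
    return side


def reconstruct_events(
    candidates: set[frozenset],
    lineages: LineagePartition,
    element_tree: ElementTree,
    host: DatedHostTree,
    mapping: pd.DataFrame,
    conflicts: list[dict] | None = None,
) -> list[HTEvent]:
    """Group flagged pairs into a minimal set of transfer events.

    Greedy parsimony: repeatedly pick the element shared by the most
    remaining candidate pairs (the hub) and bundle all its pairs into
    one event, provided the partner elements are monophyletic in the
    element tree up to intruders that are either lineage-mates of a
    partner or the hub itself (a back-transferred copy nests inside its
    source clade without breaking the grouping).  When the bundle test
    fails, the hub's single lowest-divergence pair becomes an event on
    its own and the rest are reconsidered.  Each event records its
    supporting pairs, a heuristic donor/recipient call from tree
    nesting, an age upper bound from the calibrated element tree, and
    the three criteria flags.
    """
    if not candidates:
        return []
    taxon = dict(zip(mapping["element_id"], mapping["taxon"]))

    def lineage_mates(elems: set[str]) -> set[str]:
        out = set()
        for e in elems:
            try:
                out |= set(lineages.block_of(e))
            except KeyError:
                out.add(e)
        return out

    remaining = sorted(candidates, key=sorted)
    bundles: list[tuple[str, list[frozenset]]] = []
    while remaining:
        counts: dict[str, int] = {}
        for p in remaining:
            for e in p:
                counts[e] = counts.get(e, 0) + 1
        hub = max(sorted(counts), key=lambda e: counts[e])
        mine = [p for p in remaining if hub in p]
        partners = {e for p in mine for e in p if e != hub}
        ok = True
        if len(partners) > 1:
            leafset = element_tree.mrca_leafset(partners)
            ok = leafset <= (lineage_mates(partners) | {hub})
        if ok:
            bundles.append((hub, mine))
            remaining = [p for p in remaining if hub not in p]
        else:
            lone = mine[0]
            bundles.append((hub, [lone]))
            remaining = [p for p in remaining if p != lone]

    events = []
    for hub, pairs in bundles:
        partners = frozenset(e for p in pairs for e in p if e != hub)
        if len(partners) > 1:
            hub_nested = hub in element_tree.mrca_leafset(set(partners))
        else:
            hub_nested = False  # single pair: direction undecidable
        partner_taxa = frozenset(taxon[e] for e in partners)
        if hub_nested:
            donor_taxa = partner_taxa
            recipient_taxa = frozenset({taxon[hub]})
        else:
            donor_taxa = frozenset({taxon[hub]})
            recipient_taxa = partner_taxa

        ages = [element_tree.mrca_age(set(p)) for p in pairs]
        ages = [a for a in ages if a is not None]
        age_bound = min(ages) if ages else None

        crit_ii = False
        if conflicts:
            involved = {taxon[e] for p in pairs for e in p}
            for c in conflicts:
                if involved & c["host_clade"] and involved & (
                        set(host.taxa) - set(c["host_clade"])):
                    crit_ii = True
                    break
        crit_iii = False
        for e in {e for p in pairs for e in p}:
            try:
                block = lineages.block_of(e)
            except KeyError:
                continue
            if patchy_distribution(block, mapping, host):
                crit_iii = True
                break
        events.append(HTEvent(
            hub=hub,
            partners=partners,
            donor_taxa=donor_taxa,
            recipient_taxa=recipient_taxa,
            supporting_pairs=set(pairs),
            age_upper_bound_myr=age_bound,
            criteria={"i": True, "ii": crit_ii, "iii": crit_iii},
        ))
    events.sort(key=lambda e: (
        e.age_upper_bound_myr if e.age_upper_bound_myr is not None
        else float("inf"),
        e.hub,
    ))
    return events


# ---------------------------------------------------------------------------
# model / results


class DivergenceAgeModel:
    """Divergence-versus-host-split-age model for a set of elements.

    Parameters
    ----------
    points
        The assembled (age, divergence) point set.
    nt_matrix, aa_matrix, mapping, host
        Kept for downstream steps (lineage partition, event
        reconstruction); optional when only the regression is needed.
    """

    def __init__(
        self,
        points: AgeDivergenceSet,
        nt_matrix: DistanceMatrix | None = None,
        aa_matrix: DistanceMatrix | None = None,
        mapping: pd.DataFrame | None = None,
        host: DatedHostTree | None = None,
    ) -> None:
        self.points = points
        self.nt_matrix = nt_matrix
        self.aa_matrix = aa_matrix
        self.mapping = mapping
        self.host = host

    @classmethod
    def from_distance_matrix(
        cls,
        nt_matrix: DistanceMatrix,
        mapping: pd.DataFrame,
        host: DatedHostTree,
        aa_matrix: DistanceMatrix | None = None,
        **options,
    ) -> "DivergenceAgeModel":
        points = assemble_points(
            nt_matrix, mapping, host, aa_matrix=aa_matrix, **options
        )
        return cls(points, nt_matrix=nt_matrix, aa_matrix=aa_matrix,
                   mapping=mapping, host=host)

    def fit(
        self,
        method: str = "residual",
        t_flag: float = DEFAULT_T_FLAG,
        scale: str = "mad",
        exclude: set[frozenset] | None = None,
        responses: tuple[str, ...] | None = None,
    ) -> "DivergenceAgeResults":
        """Fit, flag transfer candidates, refit after exclusion.

        When ``exclude`` is given it is used verbatim as the exclusion
        set (reproducing a published analysis independently of the
        flagging heuristic); otherwise candidates are flagged on the
        nucleotide response and the same pairs are excluded from every
        response (transfer status is a property of the element pair,
        not of the response).
        """
        if responses is None:
            responses = ("nt",) + (
                ("aa",) if any(p.d_aa is not None
                               for p in self.points.points) else ()
            )
        if exclude is not None:
            flagged = set(exclude)
        else:
            flagged = flag_candidates(
                self.points, method=method, t_flag=t_flag, scale=scale,
                response="nt",
            )
        fits = {}
        for resp in responses:
            fit_all = fit_divergence_age(self.points, response=resp)
            fit_excl = fit_divergence_age(
                self.points, exclude=flagged, response=resp,
            ) if flagged else fit_all
            fits[resp] = (fit_all, fit_excl)
        return DivergenceAgeResults(
            model=self, flagged_pairs=flagged, fits=fits,
            params={"method": method, "t_flag": t_flag, "scale": scale,
                    "explicit_exclude": exclude is not None},
        )


class DivergenceAgeResults:
    """Fitted divergence-age analysis.

    Attributes
    ----------
    flagged_pairs : set of frozenset
        Element pairs below the trend (putative transfers).
    fits : dict
        Per response (``'nt'``, ``'aa'``): a tuple of
        :class:`RegressionResult` (all points, after exclusion).
    """

    def __init__(self, model, flagged_pairs, fits, params) -> None:
        self.model = model
        self.flagged_pairs = flagged_pairs
        self.fits = fits
        self.params = params

    @property
    def regression_all(self) -> RegressionResult:
        return self.fits["nt"][0]

    @property
    def regression_refit(self) -> RegressionResult:
        return self.fits["nt"][1]

    def lineage_partition(
        self,
        indel_profiles: dict[str, set] | None = None,
        threshold: float = DEFAULT_LINEAGE_THRESHOLD,
    ) -> LineagePartition:
        if self.model.nt_matrix is None:
            raise ValueError("model was built without a distance matrix")
        elements = sorted({
            e for p in self.model.points.points for e in p.pair
        })
        return assign_lineages(
            self.model.nt_matrix, indel_profiles, threshold,
            elements=elements,
        )

    def reconstruct_events(
        self,
        element_tree: ElementTree,
        indel_profiles: dict[str, set] | None = None,
        lineage_threshold: float = DEFAULT_LINEAGE_THRESHOLD,
        s_min: float = 70.0,
    ) -> list[HTEvent]:
        if self.model.mapping is None or self.model.host is None:
            raise ValueError("model lacks mapping/host context")
        lineages = self.lineage_partition(indel_profiles,
                                          lineage_threshold)
        conflicts, _ = topology_conflicts(
            element_tree, self.model.host, self.model.mapping, s_min,
        )
        return reconstruct_events(
            self.flagged_pairs, lineages, element_tree,
            self.model.host, self.model.mapping, conflicts,
        )

    def summary(self) -> str:
        lines = [
            "Divergence vs. host split age",
            "=" * 60,
            f"points: {len(self.model.points.points)}   "
            f"flagged (putative HT): {len(self.flagged_pairs)}",
        ]
        if self.model.points.excluded_elements:
            excl = ", ".join(
                f"{k} ({v})" for k, v in
                sorted(self.model.points.excluded_elements.items())
            )
            lines.append(f"excluded elements: {excl}")
        for resp, (fa, fe) in self.fits.items():
            lines += [
                "-" * 60,
                f"[{resp}] all pairs:      R2 = {fa.r2:.3f}  "
                f"slope = {fa.slope:.5f}/Myr  p = {fa.p_value:.3g}  "
                f"n = {fa.n_points}",
                f"[{resp}] after exclusion: R2 = {fe.r2:.3f}  "
                f"slope = {fe.slope:.5f}/Myr  p = {fe.p_value:.3g}  "
                f"n = {fe.n_points}",
            ]
        if self.flagged_pairs:
            lines.append("-" * 60)
            lines.append("flagged pairs:")
            for p in sorted(self.flagged_pairs, key=sorted):
                a, b = sorted(p)
                lines.append(f"  {a} / {b}")
        return "\n".join(lines)

    def plot(self, ax=None, response: str = "nt"):
        """Scatter of divergence vs. age with both trend lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        fa, fe = self.fits[response]
        pts = [
            p for p in self.model.points.points
            if getattr(p, f"d_{response}") is not None
        ]
        ages = np.array([p.age for p in pts])
        ds = np.array([getattr(p, f"d_{response}") for p in pts])
        is_ht = np.array([p.pair in self.flagged_pairs for p in pts])
        ax.scatter(ages[~is_ht], ds[~is_ht], c="0.3", label="vertical")
        if is_ht.any():
            ax.scatter(ages[is_ht], ds[is_ht], c="crimson", marker="D",
                       label="putative HT")
        grid = np.linspace(0, ages.max() * 1.05, 50)
        ax.plot(grid, fa.predict(grid), ls=":", c="0.4",
                label=f"all (R²={fa.r2:.3f})")
        ax.plot(grid, fe.predict(grid), c="k",
                label=f"excluded (R²={fe.r2:.3f})")
        ax.set_xlabel("host split age (Myr)")
        ax.set_ylabel(f"{response} p-distance")
        ax.legend(fontsize=8)
        return ax
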
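"""Distance-based marker evaluation.

Covers the nearest-neighbor identification test, the per-sequence barcoding
gap (minimum heterospecific distance minus maximum conspecific distance),
per-species divergence summaries, the Kruskal-Wallis / Dunn comparison of
barcoding gaps between markers, and the repository-audit grouping that
screens public-database records for probable mislabels.

Tie handling in the nearest-neighbor test is strict: a query is correctly
identified only when *all* neighbors at the minimum distance are
conspecific; if some are and some are not, the call is ``ambiguous``.
Undefined (saturated or low-overlap) distances never participate in any
minimum or maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distances import DistanceMatrix

log = logging.getLogger(__name__)

CONSPECIFIC = "true"
HETEROSPECIFIC = "false"
AMBIGUOUS = "ambiguous"

_REL_TIE_TOL = 1e-12


@dataclass(frozen=True)
class NNAssignment:
    query_id: str
    neighbor_ids: tuple[str, ...]
    min_distance: float
    conspecific: str  # "true" | "false" | "ambiguous"


@dataclass(frozen=True)
class GapRecord:
    query_id: str
    max_intra: float | None  # None for singleton species
    min_inter: float | None
    gap: float | None


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    n_sequences: int
    intra_min: float | None = None
    intra_max: float | None = None
    intra_mean: float | None = None
    intra_sd: float | None = None
    inter_min: float | None = None
    inter_max: float | None = None
    inter_mean: float | None = None
    inter_sd: float | None = None


@dataclass(frozen=True)
class MarkerComparisonResult:
    kw_chi2: float
    kw_df: int
    kw_p: float
    pairwise: tuple  # (marker_a, marker_b, dunn_Z, p_raw, p_bonferroni)


@dataclass(frozen=True)
class AuditConfig:
    """Thresholds for the repository audit.

    ``intra_threshold`` is the conventional teleost intraspecific bound
    (3%); ``outlier_threshold`` marks conspecific distances so large that
    the record probably carries the wrong name.
    """

    intra_threshold: float = 0.03
    outlier_threshold: float = 0.10


@dataclass(frozen=True)
class AuditRecord:
    query_id: str
    group: int  # 1 clean, 2 ambiguous/overlapping, 3 probable mislabel
    rationale: str


def _species_arrays(dm: DistanceMatrix):
    species = np.array(dm.species_vector(), dtype=object)
    same = species[:, None] == species[None, :]
    defined = dm.defined_mask().copy()
    np.fill_diagonal(defined, False)
    return species, same, defined


def nearest_neighbor(dm: DistanceMatrix) -> list[NNAssignment]:
    """Nearest-neighbor test: is each query's closest sequence conspecific?

    All neighbors tied at the minimum defined distance are retained.
    Queries with no defined distance at all are excluded with a warning.
    """
    if dm.n < 2:
        raise ValueError("nearest-neighbor test needs at least 2 sequences")
    species, same, defined = _species_arrays(dm)
    out = []
    for i in range(dm.n):
        row_ok = defined[i]
        if not row_ok.any():
            log.warning("query %s has no defined distances; excluded",
                        dm.labels[i])
            continue
        d = dm.values[i]
        dmin = np.nanmin(np.where(row_ok, d, np.inf))
        tol = _REL_TIE_TOL * max(1.0, abs(dmin))
        tied = row_ok & (d <= dmin + tol)
        neigh = [dm.labels[j] for j in np.flatnonzero(tied)]
        consp = same[i] & tied
        if consp.sum() == tied.sum():
            call = CONSPECIFIC
        elif consp.sum() == 0:
            call = HETEROSPECIFIC
        else:
            call = AMBIGUOUS
        out.append(NNAssignment(dm.labels[i], tuple(neigh), float(dmin), call))
    return out


def percent_correct(assignments, species_of=None,
                    singleton_policy: str = "exclude") -> float:
    """Percent of queries whose nearest neighbor is conspecific.

    A singleton species can never have a conspecific neighbor; under the
    default ``exclude`` policy such queries leave the denominator, under
    ``count_incorrect`` they stay and count as failures.  ``species_of``
    is required to identify singletons.
    """
    if singleton_policy not in ("exclude", "count_incorrect"):
        raise ValueError(f"unknown singleton_policy {singleton_policy!r}")
    if not assignments:
        raise ValueError("no assignments")
    singles = set()
    if species_of is not None:
        counts: dict[str, int] = {}
        for sp in species_of.values():
            counts[sp] = counts.get(sp, 0) + 1
        singles = {
            qid for qid, sp in species_of.items() if counts[sp] == 1
        }
    considered = [
        a for a in assignments
        if singleton_policy == "count_incorrect" or a.query_id not in singles
    ]
    if not considered:
        raise ValueError("denominator empty after singleton exclusion")
    n_true = sum(1 for a in considered if a.conspecific == CONSPECIFIC)
    return 100.0 * n_true / len(considered)


def barcoding_gap(dm: DistanceMatrix) -> list[GapRecord]:
    """Per-sequence barcoding gap: min heterospecific - max conspecific.

    Positive gaps mean unambiguous identification; singletons have no
    conspecific distances and therefore no gap.
    """
    species, same, defined = _species_arrays(dm)
    out = []
    for i in range(dm.n):
        d = dm.values[i]
        intra_mask = defined[i] & same[i]
        inter_mask = defined[i] & ~same[i]
        max_intra = float(d[intra_mask].max()) if intra_mask.any() else None
        min_inter = float(d[inter_mask].min()) if inter_mask.any() else None
        gap = (
            min_inter - max_intra
            if max_intra is not None and min_inter is not None
            else None
        )
        out.append(GapRecord(dm.labels[i], max_intra, min_inter, gap))
    return out


def species_summary(dm: DistanceMatrix) -> list[SpeciesSummary]:
    """Min/max/mean/sd of intra- and interspecific divergence per species."""
    species, same, defined = _species_arrays(dm)
    order = list(dict.fromkeys(dm.species_vector()))
    triu = np.triu(np.ones((dm.n, dm.n), dtype=bool), k=1)
    out = []
    for sp in order:
        in_sp = species == sp
        n_seq = int(in_sp.sum())
        intra_cells = triu & defined & in_sp[:, None] & in_sp[None, :]
        inter_cells = defined & in_sp[:, None] & ~in_sp[None, :]
        intra = dm.values[intra_cells]
        inter = dm.values[inter_cells]

        def _stats(vals):
            if vals.size == 0:
                return (None, None, None, None)
            return (
                float(vals.min()),
                float(vals.max()),
                float(vals.mean()),
                float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            )

        i_min, i_max, i_mean, i_sd = _stats(intra)
        e_min, e_max, e_mean, e_sd = _stats(inter)
        out.append(
            SpeciesSummary(
                species=sp, n_sequences=n_seq,
                intra_min=i_min, intra_max=i_max,
                intra_mean=i_mean, intra_sd=i_sd,
                inter_min=e_min, inter_max=e_max,
                inter_mean=e_mean, inter_sd=e_sd,
            )
        )
    return out


def dunn_test(groups: dict):
    """All pairwise Dunn rank-sum Z tests with Bonferroni correction.

    Implements the standard post-hoc companion to Kruskal-Wallis: pooled
    ranks with the tie correction sum(t^3 - t) / (12 (N - 1)).
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    start = 0
    for g in names:
        mean_rank[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))
    n_pairs = len(names) * (len(names) - 1) // 2
    results = []
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            se = math.sqrt(
                (N * (N + 1) / 12.0 - tie_corr)
                * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p_raw = 2.0 * stats.norm.sf(abs(z))
            results.append((a, b, z, p_raw, min(1.0, p_raw * n_pairs)))
    return results


def compare_markers(gap_sets: dict) -> MarkerComparisonResult:
    """Kruskal-Wallis test of barcoding gaps across markers + Dunn post hoc.

    ``gap_sets`` maps marker name to a sequence of finite gap values.
    """
    if len(gap_sets) < 2:
        raise ValueError("need at least 2 markers to compare")
    clean = {}
    for name, vals in gap_sets.items():
        arr = np.asarray([v for v in vals if v is not None and math.isfinite(v)],
                         dtype=float)
        if arr.size < 2:
            raise ValueError(f"marker {name!r} has fewer than 2 finite gaps")
        clean[name] = arr
    samples = [clean[g] for g in clean]
    if np.ptp(np.concatenate(samples)) == 0:
        h, p = 0.0, 1.0  # scipy rejects fully tied data; H is 0 there
    else:
        h, p = stats.kruskal(*samples)
    return MarkerComparisonResult(
        kw_chi2=float(h),
        kw_df=len(clean) - 1,
        kw_p=float(p),
        pairwise=tuple(dunn_test(clean)),
    )


def audit_groups(dm: DistanceMatrix, assignments,
                 config: AuditConfig | None = None) -> list[AuditRecord]:
    """Classify non-singleton records into repository-audit groups.

    Group 1: nearest neighbor conspecific and the closest conspecific lies
    within ``intra_threshold`` — the record is consistent with its name.
    Group 3: *every* conspecific distance exceeds ``outlier_threshold`` —
    the record sits far from everything sharing its label (probable
    mislabel or cryptic lineage).
    Group 2: everything else (ties, overlapping ranges).
    """
    config = config or AuditConfig()
    species, same, defined = _species_arrays(dm)
    nn_by_id = {a.query_id: a for a in assignments}
    out = []
    for i in range(dm.n):
        consp_mask = defined[i] & same[i]
        n_consp_total = int(same[i].sum()) - 1  # excluding self
        if n_consp_total == 0:
            continue  # singleton: not auditable
        qid = dm.labels[i]
        consp = dm.values[i][consp_mask]
        nn = nn_by_id.get(qid)
        if consp.size == 0:
            out.append(AuditRecord(qid, 2, "conspecific_distances_undefined"))
            continue
        if (
            nn is not None
            and nn.conspecific == CONSPECIFIC
            and consp.min() <= config.intra_threshold
        ):
            out.append(AuditRecord(qid, 1, "conspecific_nn_within_threshold"))
        elif (consp > config.outlier_threshold).all():
            out.append(AuditRecord(qid, 3, "all_conspecific_beyond_outlier"))
        else:
            out.append(AuditRecord(qid, 2, "ambiguous_or_overlapping"))
    return out
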
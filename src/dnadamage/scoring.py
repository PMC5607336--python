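"""Strand-break clustering, fragment analysis and yield normalization.

Strand breaks are clustered per chromosome copy by transitive closure of
the relation |bp_i - bp_j| < d (default 10 bp), regardless of strand; a
cluster with breaks on both strands is a double-strand break (DSB), a
multi-break cluster on one strand a complex single-strand break, an
isolated break a simple SSB. Cluster complexity is the number of member
breaks.

For comparison with pulsed-field gel electrophoresis, each DSB cuts its
chromosome once (at the cluster midpoint by default); fragments shorter
than the experimental detection threshold (default 10000 bp) are removed
and the surviving fragments bound the detectable ("distant") DSB count.
The per-event DSB count is converted to DSB/Gy/Gbp with

    N_DSB/Gy/Gbp = N_DSB/event * E_1Gy / (l_bar * LET * n) * F

where E_1Gy is the energy depositing 1 Gy in the nucleus, l_bar the mean
track path, n the genome size in Gbp and F the source-coverage factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate

from .constants import (BATCH_SIZE, CLUSTER_DISTANCE_BP, COVERAGE_FACTOR,
                        E_1GY_KEV, GENOME_GBP, JOULE_PER_KEV, MEAN_CHORD_UM,
                        MIN_FRAGMENT_BP, REL_UNCERTAINTY_STOP,
                        WATER_DENSITY_KG_M3)
from .errors import ConfigurationError


@dataclass
class ScoringConfig:
    cluster_distance_bp: int = CLUSTER_DISTANCE_BP
    min_fragment_bp: int = MIN_FRAGMENT_BP
    rel_uncertainty_stop: float = REL_UNCERTAINTY_STOP
    batch_size: int = BATCH_SIZE
    cut_position: str = "midpoint"      # midpoint | min | max | first
    distant_mode: str = "adjacent"      # adjacent | interior

    def __post_init__(self):
        for name in ("cluster_distance_bp", "min_fragment_bp",
                     "rel_uncertainty_stop", "batch_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"ScoringConfig.{name} must be positive")


@dataclass
class BreakCluster:
    chromosome: str
    members: pd.DataFrame           # rows of the SB table
    classification: str             # DSB | complex_SSB | simple_SSB
    complexity: int
    bp_min: int
    bp_max: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.bp_min, self.bp_max)


def cluster_breaks(sbs: pd.DataFrame,
                   d_bp: int = CLUSTER_DISTANCE_BP) -> list[BreakCluster]:
    """Cluster deduplicated strand breaks per chromosome copy.

    Linkage is strand-agnostic: two breaks within ``< d_bp`` base pairs
    chain into one cluster (transitive closure); the strand pattern only
    decides the classification.
    """
    clusters: list[BreakCluster] = []
    if len(sbs) == 0:
        return clusters
    sbs = sbs.drop_duplicates(subset=["chromosome", "bp", "strand"])
    for chrom, group in sbs.groupby("chromosome", sort=True):
        g = group.sort_values(["bp", "strand"], kind="stable")
        bp = g["bp"].to_numpy()
        breaks_at = np.nonzero(np.diff(bp) >= d_bp)[0] + 1
        for part in np.split(np.arange(len(g)), breaks_at):
            members = g.iloc[part]
            strands = set(members["strand"])
            if len(members) >= 2 and len(strands) == 2:
                cls = "DSB"
            elif len(members) >= 2:
                cls = "complex_SSB"
            else:
                cls = "simple_SSB"
            clusters.append(BreakCluster(
                chromosome=str(chrom), members=members, classification=cls,
                complexity=int(len(members)),
                bp_min=int(members["bp"].min()),
                bp_max=int(members["bp"].max())))
    return clusters


def clusters_table(clusters: list[BreakCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.chromosome, c.classification, c.complexity, c.bp_min, c.bp_max)
         for c in clusters],
        columns=["chromosome", "classification", "complexity",
                 "bp_min", "bp_max"])


def _cut_position(cluster: BreakCluster, mode: str) -> int:
    if mode == "midpoint":
        return (cluster.bp_min + cluster.bp_max) // 2
    if mode == "min":
        return cluster.bp_min
    if mode == "max":
        return cluster.bp_max
    if mode == "first":
        return int(cluster.members["bp"].iloc[0])
    raise ConfigurationError(f"unknown cut position mode {mode!r}")


def compute_fragments(dsb_clusters: list[BreakCluster],
                      chromosome_lengths: dict[str, int],
                      cut_position: str = "midpoint") -> pd.DataFrame:
    """Fragment table from one cut per DSB; lengths sum to each chromosome.

    Every chromosome copy in ``chromosome_lengths`` contributes k+1
    fragments for k DSBs (a copy without DSBs is one full-length fragment).
    """
    cuts: dict[str, list[int]] = {c: [] for c in chromosome_lengths}
    for cl in dsb_clusters:
        if cl.classification != "DSB":
            continue
        if cl.chromosome not in chromosome_lengths:
            raise ConfigurationError(
                f"DSB on unknown chromosome {cl.chromosome!r}")
        pos = _cut_position(cl, cut_position)
        length = chromosome_lengths[cl.chromosome]
        if not 0 <= pos <= length:
            raise ConfigurationError(
                f"cut at {pos} outside chromosome {cl.chromosome} "
                f"(length {length})")
        cuts[cl.chromosome].append(pos)
    rows = []
    for chrom in sorted(chromosome_lengths):
        length = chromosome_lengths[chrom]
        edges = [0] + sorted(cuts[chrom]) + [length]
        for start, end in zip(edges[:-1], edges[1:]):
            rows.append((chrom, start, end, end - start))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                       "length"])


def apply_detection_threshold(fragments: pd.DataFrame,
                              min_bp: int = MIN_FRAGMENT_BP,
                              mode: str = "adjacent"):
    """PFGE resolution filter and detectable-DSB reconstruction.

    Fragments strictly shorter than ``min_bp`` are removed (a fragment of
    exactly ``min_bp`` survives). The detectable ("distant") DSB count is
    reconstructed from the surviving fragments: in ``adjacent`` mode a cut
    counts when at least one of its two flanking fragments survives; in the
    stricter ``interior`` mode both must survive.

    Returns (surviving fragments, distant DSB count).
    """
    if mode not in ("adjacent", "interior"):
        raise ConfigurationError(f"unknown distant-DSB mode {mode!r}")
    survive = fragments["length"] >= min_bp
    kept = fragments[survive].reset_index(drop=True)
    distant = 0
    for _, group in fragments.groupby("chromosome", sort=False):
        s = survive[group.index].to_numpy()
        for i in range(len(s) - 1):       # cut i between fragment i and i+1
            ok = (s[i] or s[i + 1]) if mode == "adjacent" else (s[i] and s[i + 1])
            distant += bool(ok)
    return kept, int(distant)


# ---------------------------------------------------------------------------
# Geometry-derived normalization constants
# ---------------------------------------------------------------------------

def compute_E1Gy(half_axes_um, density_kg_m3: float = WATER_DENSITY_KG_M3
                 ) -> float:
    """Energy (keV) depositing a mean dose of 1 Gy in the ellipsoid."""
    a, b, c = (float(x) for x in half_axes_um)
    if min(a, b, c) <= 0:
        raise ConfigurationError("half axes must be positive")
    volume_m3 = 4.0 / 3.0 * np.pi * a * b * c * 1e-18
    return volume_m3 * density_kg_m3 * 1.0 / JOULE_PER_KEV


def coverage_fraction(half_axes_um, rect_x_um: float, rect_y_um: float
                      ) -> float:
    """Fraction of the ellipsoid volume shadowed by the source rectangle."""
    a, b, _ = (float(x) for x in half_axes_um)
    if min(a, b) <= 0 or rect_x_um <= 0 or rect_y_um <= 0:
        raise ConfigurationError("dimensions must be positive")
    u0 = min(rect_x_um / 2.0 / a, 1.0)
    v0 = min(rect_y_um / 2.0 / b, 1.0)
    val, _ = integrate.dblquad(
        lambda v, u: np.sqrt(max(1.0 - u * u - v * v, 0.0)),
        0.0, u0, 0.0, lambda u: min(v0, np.sqrt(max(1.0 - u * u, 0.0))))
    return 4.0 * 2.0 * val / (4.0 * np.pi / 3.0)


def covered_hit_area_um2(half_axes_um, rect_x_um: float, rect_y_um: float
                         ) -> float:
    """Area of the ellipse cross-section under the source rectangle."""
    a, b, _ = (float(x) for x in half_axes_um)
    u0 = min(rect_x_um / 2.0 / a, 1.0)
    v0 = min(rect_y_um / 2.0 / b, 1.0)
    val, _ = integrate.dblquad(
        lambda v, u: 1.0,
        0.0, u0, 0.0, lambda u: min(v0, np.sqrt(max(1.0 - u * u, 0.0))))
    return 4.0 * val * a * b


def mean_chord(half_axes_um, rect_x_um: float | None = None,
               rect_y_um: float | None = None) -> float:
    """Mean vertical chord (um) of tracks from the rectangle that hit.

    With no rectangle (full projection) this is the classic volume /
    projected-area ratio; with a source rectangle it is covered volume over
    covered hit area.
    """
    a, b, c = (float(x) for x in half_axes_um)
    if rect_x_um is None or rect_y_um is None:
        return (4.0 / 3.0 * np.pi * a * b * c) / (np.pi * a * b)
    frac = coverage_fraction(half_axes_um, rect_x_um, rect_y_um)
    area = covered_hit_area_um2(half_axes_um, rect_x_um, rect_y_um)
    return frac * 4.0 / 3.0 * np.pi * a * b * c / area


# ---------------------------------------------------------------------------
# Yield normalization and convergence control
# ---------------------------------------------------------------------------

@dataclass
class YieldParams:
    E_1Gy_keV: float = E_1GY_KEV
    l_bar_um: float = MEAN_CHORD_UM
    n_Gbp: float = GENOME_GBP
    F: float = COVERAGE_FACTOR
    let_keV_per_um: float = 27.2

    def __post_init__(self):
        if self.let_keV_per_um <= 0:
            raise ConfigurationError("LET must be positive")
        for name in ("E_1Gy_keV", "l_bar_um", "n_Gbp", "F"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"YieldParams.{name} must be positive")


def dsb_yield_normalization(n_dsb_per_event: float,
                            params: YieldParams) -> float:
    """DSB per Gy per Gbp from the per-event DSB count."""
    return (n_dsb_per_event * params.E_1Gy_keV
            / (params.l_bar_um * params.let_keV_per_um * params.n_Gbp)
            * params.F)


@dataclass
class YieldResult:
    n_dsb_per_event: float
    se_per_event: float
    n_dsb_gy_gbp: float
    n_events: int
    n_batches: int
    converged: bool
    batch_means: list = field(default_factory=list)
    breakdown: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(
            n_dsb_per_event=self.n_dsb_per_event,
            se_per_event=self.se_per_event,
            n_dsb_gy_gbp=self.n_dsb_gy_gbp,
            n_events=self.n_events, n_batches=self.n_batches,
            converged=self.converged, batch_means=list(self.batch_means),
            breakdown=dict(self.breakdown))


def run_until_converged(batch_fn, config: ScoringConfig,
                        params: YieldParams,
                        min_batches: int = 2,
                        max_batches: int = 100) -> YieldResult:
    """Add batches of events until the DSB-yield uncertainty is small.

    ``batch_fn(batch_index)`` returns the per-event DSB counts of one batch
    of ``config.batch_size`` events. Stops when the standard error of the
    batch means falls below ``rel_uncertainty_stop`` times the mean (at
    least ``min_batches`` batches); a zero mean after ``max_batches``
    returns unconverged.
    """
    batch_means: list[float] = []
    n_events = 0
    converged = False
    for b in range(max_batches):
        counts = np.asarray(batch_fn(b), dtype=float)
        n_events += len(counts)
        batch_means.append(float(counts.mean()) if len(counts) else 0.0)
        if len(batch_means) < min_batches:
            continue
        mean = float(np.mean(batch_means))
        se = float(np.std(batch_means, ddof=1) / np.sqrt(len(batch_means)))
        if mean > 0 and se <= config.rel_uncertainty_stop * mean:
            converged = True
            break
        if mean == 0 and se == 0 and len(batch_means) >= min_batches:
            break
    mean = float(np.mean(batch_means))
    se = (float(np.std(batch_means, ddof=1) / np.sqrt(len(batch_means)))
          if len(batch_means) > 1 else 0.0)
    return YieldResult(
        n_dsb_per_event=mean, se_per_event=se,
        n_dsb_gy_gbp=dsb_yield_normalization(mean, params),
        n_events=n_events, n_batches=len(batch_means),
        converged=converged, batch_means=batch_means)
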
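"""Aberrant splicing: intron clustering, one-vs-rest testing, psi and
event classification.

Junctions (introns supported by split reads) are clustered into
connected components over shared donor/acceptor sites, annotation-free.
Each cluster is tested per patient with a Dirichlet-multinomial
likelihood-ratio test of patient-specific versus shared junction
proportions. Per cent spliced in values quantify each junction's share
of its donor (psi5) and acceptor (psi3) site, and significant clusters
are classified into the event taxonomy (exon skipping, truncation,
elongation, new exon, complex) against an exon annotation.

Intron coordinates are 0-based half-open; the donor is the intron start
side and the acceptor the intron end side. Intron retention cannot be
seen in split reads and is not attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import gammaln

from .io import ValidationError, read_junction_table, JUNCTION_KEY
from .multitest import hochberg_adjust

__all__ = [
    "load_junctions",
    "IntronCluster",
    "cluster_introns",
    "compute_psi",
    "PsiTable",
    "annotate_splice_sites",
    "test_cluster_one_vs_rest",
    "classify_event",
    "psi_site_observations",
    "private_exon_weak_enrichment",
    "SplicingOutlierModel",
    "SplicingOutlierResults",
]

EVENT_CLASSES = [
    "exon skipping",
    "exon truncation",
    "exon elongation",
    "new exon",
    "complex",
    "unclassified",
]

GAMMA_FLOOR = 0.01  # Dirichlet-multinomial concentration floor


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_junctions(path, min_mapq: int = 10, coords: str = "bed") -> pd.DataFrame:
    """Load a junction count table.

    ``coords="star"`` converts STAR ``SJ.out.tab``-style 1-based
    inclusive intron records to 0-based half-open (start-1, end).
    Duplicate (chrom, donor, acceptor, strand) rows are merged by
    summation and rows with acceptor <= donor are rejected with a
    warning. ``min_mapq`` documents the split-read mapping-quality
    filter (> 10) applied when counts are extracted from alignments;
    counts in the table are taken as given.
    """
    tab = read_junction_table(path)
    if coords == "star":
        tab = tab.assign(donor=tab["donor"] - 1)
    elif coords != "bed":
        raise ValueError("coords must be 'bed' or 'star'")
    bad = tab["acceptor"] <= tab["donor"]
    if bad.any():
        warnings.warn(f"rejecting {int(bad.sum())} junction rows with acceptor <= donor")
        tab = tab[~bad]
    sample_cols = [c for c in tab.columns if c not in JUNCTION_KEY]
    tab = tab.groupby(JUNCTION_KEY, as_index=False, sort=True)[sample_cols].sum()
    return tab.reset_index(drop=True)


# ---------------------------------------------------------------------------
# intron clustering
# ---------------------------------------------------------------------------

@dataclass
class IntronCluster:
    cluster_id: str
    members: list = field(default_factory=list)  # row indices into the table
    total_reads: int = 0


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _connected_components(tab: pd.DataFrame, idx: np.ndarray) -> list[list[int]]:
    uf = _UnionFind(len(idx))
    site_map: dict[tuple, int] = {}
    for local, row in enumerate(idx):
        chrom = tab.at[row, "chrom"]
        strand = tab.at[row, "strand"]
        for key in (
            (chrom, strand, "D", tab.at[row, "donor"]),
            (chrom, strand, "A", tab.at[row, "acceptor"]),
        ):
            if key in site_map:
                uf.union(local, site_map[key])
            else:
                site_map[key] = local
    comps: dict[int, list[int]] = {}
    for local, row in enumerate(idx):
        comps.setdefault(uf.find(local), []).append(row)
    return list(comps.values())


def cluster_introns(
    junctions: pd.DataFrame,
    minclureads: int = 30,
    maxintronlen: int = 500_000,
    mincluratio: float = 1e-5,
) -> list[IntronCluster]:
    """Cluster introns into connected components over shared sites.

    Introns longer than ``maxintronlen`` are removed first; junctions
    contributing less than ``mincluratio`` of their cluster's cohort
    total are pruned iteratively (re-forming components); clusters whose
    total is below ``minclureads`` are dropped. Output ordering is
    deterministic (by cluster coordinates) and independent of input
    order.
    """
    sample_cols = [c for c in junctions.columns if c not in JUNCTION_KEY]
    totals = junctions[sample_cols].sum(axis=1)
    keep = (junctions["acceptor"] - junctions["donor"]) <= maxintronlen
    idx = junctions.index[keep].to_numpy()

    while True:
        comps = _connected_components(junctions, idx)
        pruned = []
        changed = False
        for comp in comps:
            cluster_total = totals.loc[comp].sum()
            if cluster_total <= 0:
                changed = True
                continue
            ok = [r for r in comp if totals.loc[r] / cluster_total >= mincluratio]
            if len(ok) < len(comp):
                changed = True
            pruned.extend(ok)
        idx = np.asarray(sorted(pruned))
        if not changed:
            break

    clusters = []
    for comp in _connected_components(junctions, idx):
        total = int(totals.loc[comp].sum())
        if total < minclureads:
            continue
        comp = sorted(comp)
        first = junctions.loc[comp[0]]
        cid = f"{first['chrom']}:{int(junctions.loc[comp, 'donor'].min())}-" \
              f"{int(junctions.loc[comp, 'acceptor'].max())}"
        clusters.append(IntronCluster(cid, comp, total))
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


# ---------------------------------------------------------------------------
# per cent spliced in
# ---------------------------------------------------------------------------

@dataclass
class PsiTable:
    """psi5/psi3 shares per junction and sample, with site denominators.

    psi5(D, A) = n(D, A) / sum_A' n(D, A'); psi3 analogously over
    donors at the acceptor. Entries are NaN where the denominator is 0.
    """

    psi5: pd.DataFrame
    psi3: pd.DataFrame
    n5: pd.DataFrame
    n3: pd.DataFrame


def compute_psi(junctions: pd.DataFrame) -> PsiTable:
    sample_cols = [c for c in junctions.columns if c not in JUNCTION_KEY]
    counts = junctions[sample_cols].astype(float)
    donor_key = list(zip(junctions["chrom"], junctions["strand"], junctions["donor"]))
    acceptor_key = list(
        zip(junctions["chrom"], junctions["strand"], junctions["acceptor"])
    )
    n5 = counts.groupby(pd.Index(donor_key), sort=False).transform("sum")
    n3 = counts.groupby(pd.Index(acceptor_key), sort=False).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        psi5 = counts / n5.where(n5 > 0)
        psi3 = counts / n3.where(n3 > 0)
    return PsiTable(psi5=psi5, psi3=psi3, n5=n5, n3=n3)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_splice_sites(
    junctions: pd.DataFrame, exons: pd.DataFrame
) -> pd.DataFrame:
    """Annotation status per junction.

    A donor (intron start, 0-based) is annotated iff it equals an exon
    end; an acceptor (intron end) iff it equals an exon start - 1.
    When the junction strand is known only same-strand exons match; for
    unknown strand ('.' or '*') either boundary orientation on either
    strand counts. Returns donor_annotated, acceptor_annotated and the
    group s (number of annotated sides).
    """
    by_strand_end: dict[tuple, set] = {}
    by_strand_start: dict[tuple, set] = {}
    for row in exons.itertuples(index=False):
        by_strand_end.setdefault((row.chrom, row.strand), set()).add(row.end)
        by_strand_start.setdefault((row.chrom, row.strand), set()).add(row.start - 1)

    def any_boundary(chrom, pos):
        return any(
            pos in s
            for key, s in list(by_strand_end.items()) + list(by_strand_start.items())
            if key[0] == chrom
        )

    donor_ann, acceptor_ann = [], []
    for row in junctions.itertuples(index=False):
        if row.strand in ("+", "-"):
            d = row.donor in by_strand_end.get((row.chrom, row.strand), set())
            a = row.acceptor in by_strand_start.get((row.chrom, row.strand), set())
        else:
            d = any_boundary(row.chrom, row.donor)
            a = any_boundary(row.chrom, row.acceptor)
        donor_ann.append(d)
        acceptor_ann.append(a)
    out = pd.DataFrame(
        {
            "donor_annotated": donor_ann,
            "acceptor_annotated": acceptor_ann,
        },
        index=junctions.index,
    )
    out["s"] = out["donor_annotated"].astype(int) + out["acceptor_annotated"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Dirichlet-multinomial one-vs-rest test
# ---------------------------------------------------------------------------

def _dm_loglik(Y: np.ndarray, gamma: float, p: np.ndarray) -> float:
    """Dirichlet-multinomial log-likelihood for count rows Y (S x J),
    concentration gamma and proportions p (multinomial coefficient
    omitted: it cancels in likelihood ratios)."""
    a = gamma * p
    N = Y.sum(axis=1)
    return float(
        (gammaln(gamma) - gammaln(N + gamma)).sum()
        + (gammaln(Y + a) - gammaln(a)).sum()
    )


def _softmax_p(logits: np.ndarray) -> np.ndarray:
    z = np.concatenate([[0.0], logits])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _fit_dm(Y: np.ndarray, groups: list[np.ndarray]) -> float:
    """Maximise the DM log-likelihood with one proportion vector per
    sample group and a concentration shared across groups
    (parametrised as log gamma plus softmax logits; analytic
    gradient)."""
    from scipy.special import digamma

    J = Y.shape[1]
    pooled = Y.sum(axis=0) + 0.5
    pooled = pooled / pooled.sum()
    init_logits = np.log(pooled[1:] / pooled[0])

    def unpack(theta):
        gamma = np.exp(theta[0])
        ps = []
        for g in range(len(groups)):
            logits = theta[1 + g * (J - 1): 1 + (g + 1) * (J - 1)]
            ps.append(_softmax_p(logits))
        return gamma, ps

    def nll_and_grad(theta):
        gamma, ps = unpack(theta)
        ll = 0.0
        grad = np.zeros_like(theta)
        dll_dtheta0 = 0.0
        for g, (rows, p) in enumerate(zip(groups, ps)):
            Yg = Y[rows]
            a = gamma * p
            N = Yg.sum(axis=1)
            ll += _dm_loglik(Yg, gamma, p)
            Gj = (digamma(Yg + a) - digamma(a)).sum(axis=0)
            dll_dgamma = (digamma(gamma) - digamma(N + gamma)).sum() + (p * Gj).sum()
            dll_dtheta0 += gamma * dll_dgamma
            Gbar = (p * Gj).sum()
            dl = gamma * p[1:] * (Gj[1:] - Gbar)
            grad[1 + g * (J - 1): 1 + (g + 1) * (J - 1)] = -dl
        grad[0] = -dll_dtheta0
        return -ll, grad

    theta0 = np.concatenate([[np.log(10.0)], np.tile(init_logits, len(groups))])
    bounds = [(np.log(GAMMA_FLOOR), np.log(1e8))] + [(-30, 30)] * (
        (J - 1) * len(groups)
    )
    best = minimize(nll_and_grad, theta0, jac=True, method="L-BFGS-B",
                    bounds=bounds, options={"maxiter": 1000, "ftol": 1e-14})
    return -best.fun


def test_cluster_one_vs_rest(
    cluster_counts: np.ndarray, patient_cols: np.ndarray
) -> tuple[float, float]:
    """Dirichlet-multinomial LRT of patient-specific junction
    proportions against proportions shared with the rest of the cohort.

    ``cluster_counts`` is samples x junctions; ``patient_cols`` a
    boolean mask of the patient's samples (replicates allowed). Returns
    (p, statistic) from a chi-square with J - 1 degrees of freedom;
    (nan, nan) when the patient has no reads in the cluster.
    """
    Y = np.asarray(cluster_counts, dtype=float)
    mask = np.asarray(patient_cols, dtype=bool)
    if Y.shape[1] < 2:
        raise ValidationError("cluster must contain at least 2 junctions")
    if Y[mask].sum() == 0:
        return np.nan, np.nan
    rows_all = np.arange(Y.shape[0])
    ll_null = _fit_dm(Y, [rows_all])
    ll_alt = _fit_dm(Y, [rows_all[mask], rows_all[~mask]])
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(stats.chi2.sf(stat, df=Y.shape[1] - 1))
    return p, stat


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------

def _exon_intervals(exons: pd.DataFrame, chrom: str) -> list[tuple[int, int]]:
    sub = exons[exons["chrom"] == chrom]
    # 0-based half-open
    return [(int(s) - 1, int(e)) for s, e in zip(sub["start"], sub["end"])]


def classify_event(
    cluster_junctions: pd.DataFrame,
    patient_delta: np.ndarray,
    annotation_flags: pd.DataFrame,
    exons: pd.DataFrame,
) -> tuple[str, list[str]]:
    """Rule-based event class for a significant cluster.

    ``patient_delta`` is the patient-minus-rest difference in cluster
    junction proportions; the patient-dominant junction is its argmax.
    Returns the event class and the site keys (``"<row>:5"`` /
    ``"<row>:3"``) of the sites that define the event (for new exons,
    the shared annotated sides of the two defining junctions, whose
    psi classes measure splice-site strength).
    """
    order = np.argsort(-np.asarray(patient_delta))
    rows = cluster_junctions.index.to_numpy()
    dom = cluster_junctions.loc[rows[order[0]]]
    dom_flags = annotation_flags.loc[rows[order[0]]]
    chrom = dom["chrom"]
    intervals = _exon_intervals(exons, chrom)

    def inside_exon(pos):
        return any(e0 < pos < e1 for e0, e1 in intervals)

    def overlaps_span(lo, hi):
        return any(e0 < hi and e1 > lo for e0, e1 in intervals)

    # new exon: two patient-elevated junctions with unannotated inner
    # sites flanking a novel interval, outer sides on annotated exons
    if len(order) >= 2 and patient_delta[order[1]] > 0:
        j1 = cluster_junctions.loc[rows[order[0]]]
        j2 = cluster_junctions.loc[rows[order[1]]]
        f1 = annotation_flags.loc[rows[order[0]]]
        f2 = annotation_flags.loc[rows[order[1]]]
        for (ja, fa, ra), (jb, fb, rb) in (
            ((j1, f1, rows[order[0]]), (j2, f2, rows[order[1]])),
            ((j2, f2, rows[order[1]]), (j1, f1, rows[order[0]])),
        ):
            if (
                ja["acceptor"] < jb["donor"]
                and fa["donor_annotated"]
                and fb["acceptor_annotated"]
                and not fa["acceptor_annotated"]
                and not fb["donor_annotated"]
                and not inside_exon(ja["acceptor"])
                and not inside_exon(jb["donor"])
            ):
                return "new exon", [f"{ra}:5", f"{rb}:3"]

    d_ann = bool(dom_flags["donor_annotated"])
    a_ann = bool(dom_flags["acceptor_annotated"])
    donor, acceptor = int(dom["donor"]), int(dom["acceptor"])
    if d_ann and a_ann:
        skipped = any(donor <= e0 and e1 <= acceptor for e0, e1 in intervals)
        if skipped:
            return "exon skipping", [f"{rows[order[0]]}:3"]
        return "complex", []
    if d_ann != a_ann:
        novel_pos = acceptor if d_ann else donor
        side = f"{rows[order[0]]}:{'5' if d_ann else '3'}"
        if inside_exon(novel_pos):
            return "exon truncation", [side]
        return "exon elongation", [side]
    if not overlaps_span(donor, acceptor):
        return "unclassified", []
    return "complex", []


# ---------------------------------------------------------------------------
# site observations for the mixture + weak-site enrichment
# ---------------------------------------------------------------------------

def psi_site_observations(
    junctions: pd.DataFrame, annotation_flags: pd.DataFrame
) -> pd.DataFrame:
    """One (n, N) observation per junction side, pooled over samples.

    n is the junction's cohort-total count; N the cohort total of its
    donor (side "5") or acceptor (side "3"). The annotation group s is
    the junction's number of annotated sides. Sides with N = 0 are
    dropped. Site keys are ``"<row>:5"`` / ``"<row>:3"``.
    """
    sample_cols = [c for c in junctions.columns if c not in JUNCTION_KEY]
    n = junctions[sample_cols].sum(axis=1)
    donor_key = list(zip(junctions["chrom"], junctions["strand"], junctions["donor"]))
    acceptor_key = list(
        zip(junctions["chrom"], junctions["strand"], junctions["acceptor"])
    )
    n5 = n.groupby(pd.Index(donor_key), sort=False).transform("sum")
    n3 = n.groupby(pd.Index(acceptor_key), sort=False).transform("sum")
    frames = []
    for side, N in (("5", n5), ("3", n3)):
        frames.append(
            pd.DataFrame(
                {
                    "site": [f"{i}:{side}" for i in junctions.index],
                    "junction": junctions.index,
                    "side": side,
                    "n": n.to_numpy(),
                    "N": N.to_numpy(),
                    "s": annotation_flags["s"].to_numpy(),
                }
            )
        )
    obs = pd.concat(frames, ignore_index=True)
    return obs[obs["N"] > 0].reset_index(drop=True)


def private_exon_weak_enrichment(
    calls: pd.DataFrame, site_classes: pd.Series
) -> tuple[float, float]:
    """Fraction of private (new exon) event sites classed weak, and its
    fold over the cohort-wide weak fraction.

    ``calls`` needs event_class and event_sites (list of site keys);
    ``site_classes`` maps site key -> class name. Returns (nan, nan)
    when there is no private event.
    """
    private = calls[calls["event_class"] == "new exon"]
    sites = [s for row in private["event_sites"] for s in row if s in site_classes.index]
    if not sites:
        return np.nan, np.nan
    fraction_weak = float(np.mean(site_classes.loc[sites] == "weak"))
    cohort_weak = float(np.mean(site_classes == "weak"))
    fold = fraction_weak / cohort_weak if cohort_weak > 0 else np.inf
    return fraction_weak, fold


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SplicingOutlierModel:
    """One-vs-rest differential splicing over intron clusters.

    Parameters mirror the clustering defaults (minclureads=30,
    maxintronlen=500000, mincluratio=1e-5) tuned for rare, private
    events.
    """

    def __init__(
        self,
        junctions: pd.DataFrame,
        annotation: pd.DataFrame,
        exons: pd.DataFrame | None = None,
        minclureads: int = 30,
        maxintronlen: int = 500_000,
        mincluratio: float = 1e-5,
    ):
        self.junctions = junctions.reset_index(drop=True)
        self.annotation = annotation
        self.exons = exons if exons is not None else pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "gene_id", "exon_id"]
        )
        self.sample_cols = [
            c for c in self.junctions.columns if c not in JUNCTION_KEY
        ]
        missing = [s for s in self.sample_cols if s not in annotation.index]
        if missing:
            raise ValidationError(
                "junction samples missing from annotation: " + ", ".join(missing)
            )
        self.clusters = cluster_introns(
            self.junctions, minclureads, maxintronlen, mincluratio
        )
        self.flags = annotate_splice_sites(self.junctions, self.exons)

    @property
    def patients(self) -> list[str]:
        groups = self.annotation.loc[self.sample_cols, "group_id"].astype(str)
        return list(dict.fromkeys(groups))

    def fit(self, patient: str | None = None) -> "SplicingOutlierResults":
        patients = [str(patient)] if patient is not None else self.patients
        groups = self.annotation.loc[self.sample_cols, "group_id"].astype(str)
        masks = {}
        for pat in patients:
            mask = (groups == pat).to_numpy()
            if not mask.any():
                raise ValidationError(f"patient {pat!r} not found in annotation")
            masks[pat] = mask
        records = []
        rows_all = np.arange(len(self.sample_cols))
        for cluster in self.clusters:
            sub = self.junctions.loc[cluster.members]
            Y = sub[self.sample_cols].to_numpy(float).T  # samples x junctions
            if Y.shape[1] < 2:
                continue
            ll_null = _fit_dm(Y, [rows_all])  # shared across patients
            for pat, mask in masks.items():
                if Y[mask].sum() == 0:
                    p, stat = np.nan, np.nan
                else:
                    ll_alt = _fit_dm(Y, [rows_all[mask], rows_all[~mask]])
                    stat = max(0.0, 2.0 * (ll_alt - ll_null))
                    p = float(stats.chi2.sf(stat, df=Y.shape[1] - 1))
                records.append(
                    {
                        "cluster": cluster.cluster_id,
                        "sample": pat,
                        "pvalue": p,
                        "statistic": stat,
                        "n_junctions": Y.shape[1],
                        "_members": cluster.members,
                        "_mask": mask,
                    }
                )
        table = pd.DataFrame(records)
        if len(table):
            table["padj"] = np.nan
            for pat in patients:
                rows = table["sample"] == pat
                table.loc[rows, "padj"] = hochberg_adjust(
                    table.loc[rows, "pvalue"].to_numpy()
                )
        return SplicingOutlierResults(self, table)


class SplicingOutlierResults:
    """Cluster-level one-vs-rest splicing tests with Hochberg-adjusted
    p-values; ``call_events`` classifies significant clusters."""

    def __init__(self, model: SplicingOutlierModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    def call_events(self, padj_threshold: float = 0.05) -> pd.DataFrame:
        if not len(self.table):
            return pd.DataFrame(
                columns=[
                    "cluster", "sample", "pvalue", "padj", "event_class",
                    "event_sites", "dominant_junction",
                ]
            )
        calls = []
        for rec in self.table.to_dict("records"):
            sig = (
                np.isfinite(rec["pvalue"]) and rec["padj"] < padj_threshold
            )
            if not sig:
                continue
            sub = self.model.junctions.loc[rec["_members"]]
            Y = sub[self.model.sample_cols].to_numpy(float).T
            mask = rec["_mask"]
            pat_tot, rest_tot = Y[mask].sum(), Y[~mask].sum()
            p_pat = Y[mask].sum(axis=0) / max(pat_tot, 1.0)
            p_rest = Y[~mask].sum(axis=0) / max(rest_tot, 1.0)
            delta = p_pat - p_rest
            event_class, sites = classify_event(
                sub, delta, self.model.flags, self.model.exons
            )
            calls.append(
                {
                    "cluster": rec["cluster"],
                    "sample": rec["sample"],
                    "pvalue": rec["pvalue"],
                    "padj": rec["padj"],
                    "event_class": event_class,
                    "event_sites": sites,
                    "dominant_junction": int(sub.index[np.argmax(delta)]),
                }
            )
        return pd.DataFrame(
            calls,
            columns=[
                "cluster", "sample", "pvalue", "padj", "event_class",
                "event_sites", "dominant_junction",
            ],
        )

    def summary(self) -> str:
        calls = self.call_events()
        per_sample = (
            calls.groupby("sample").size()
            if len(calls)
            else pd.Series(dtype=float)
        )
        lines = [
            "Aberrant splicing (Dirichlet-multinomial one-vs-rest LRT)",
            f"  clusters tested:   {self.table['cluster'].nunique() if len(self.table) else 0}",
            f"  significant calls: {len(calls)}",
            f"  median per sample: {per_sample.median() if len(per_sample) else 0:g}",
        ]
        return "\n".join(lines)
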
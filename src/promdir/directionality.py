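"""Classification of active genes as bi- or unidirectionally transcribed.

Two independent rules are applied to every active gene and then combined:

* gene-model rule ("ensembl"): bidirectional iff another gene's TSS lies on
  the opposite strand within 1 kb (point-to-point distance);
* CAGE rule: bidirectional iff a CAGE cluster lies on the opposite strand
  within 1 kb (point-to-interval distance).

A gene is unidirectional (per rule) if active and not bidirectional. Only
genes on which the two rules agree keep a combined class; disagreements are
"excluded". Inactive genes carry "n/a" everywhere.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomicInterval

ACTIVITY_DISTANCE = 10
BIDIRECTIONAL_DISTANCE = 1000


def interval_distance(tss: int, iv: GenomicInterval) -> int:
    """Minimum absolute distance from the TSS to any base of the interval."""
    return max(iv.start - tss, tss - (iv.end - 1), 0)


def _cluster_index(clusters: Sequence[GenomicInterval]):
    """Per (chrom, strand): sorted starts and (sorted-by-start) ends."""
    idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[tuple[str, str], list[GenomicInterval]] = {}
    for c in clusters:
        grouped.setdefault((c.chrom, c.strand), []).append(c)
    for key, ivs in grouped.items():
        ivs.sort(key=lambda v: v.start)
        idx[key] = (np.array([v.start for v in ivs]),
                    np.array([v.end for v in ivs]),
                    ivs)  # type: ignore[assignment]
    return idx


def _any_cluster_within(idx, chrom: str, strand: str, tss: int, dist: int) -> bool:
    entry = idx.get((chrom, strand))
    if entry is None:
        return False
    starts, ends, _ = entry
    # candidate clusters with start <= tss + dist; check end-side distance
    hi = np.searchsorted(starts, tss + dist, side="right")
    return bool((ends[:hi] > tss - dist).any())


def call_active(
    genes: Sequence[GeneModel],
    clusters: Sequence[GenomicInterval],
    activity_distance: int = ACTIVITY_DISTANCE,
) -> set[str]:
    """Gene IDs with a same-strand cluster within ``activity_distance`` bp of the TSS."""
    idx = _cluster_index(clusters)
    return {
        g.gene_id
        for g in genes
        if _any_cluster_within(idx, g.chrom, g.strand, g.tss, activity_distance)
    }


def annotate(
    genes: Sequence[GeneModel],
    clusters: Sequence[GenomicInterval],
    sense_tags: Mapping[str, int] | None = None,
    antisense_tags: Mapping[str, int] | None = None,
    activity_distance: int = ACTIVITY_DISTANCE,
    bidirectional_distance: int = BIDIRECTIONAL_DISTANCE,
) -> pd.DataFrame:
    """Annotate every gene with activity and directionality classes.

    Returns a DataFrame indexed by gene_id with columns active,
    class_ensembl, class_cage, class_combined, sense_tags, antisense_tags,
    has_upstream_alt_tss.
    """
    active = call_active(genes, clusters, activity_distance)
    idx = _cluster_index(clusters)

    # opposite-strand gene TSSs, sorted per (chrom, strand)
    tss_index: dict[tuple[str, str], np.ndarray] = {}
    for g in genes:
        tss_index.setdefault((g.chrom, g.strand), []).append(g.tss)  # type: ignore
    tss_index = {k: np.sort(np.asarray(v)) for k, v in tss_index.items()}

    rows = []
    no_alt = set(filter_no_upstream_alt_tss(
        genes, clusters, activity_distance, bidirectional_distance))
    for g in genes:
        is_active = g.gene_id in active
        if not is_active:
            ce = cc = comb = "n/a"
        else:
            opp = "-" if g.strand == "+" else "+"
            opp_tss = tss_index.get((g.chrom, opp))
            ens_bi = False
            if opp_tss is not None:
                lo = np.searchsorted(opp_tss, g.tss - bidirectional_distance, "left")
                hi = np.searchsorted(opp_tss, g.tss + bidirectional_distance, "right")
                ens_bi = hi > lo
            cage_bi = _any_cluster_within(
                idx, g.chrom, opp, g.tss, bidirectional_distance)
            ce = "bi" if ens_bi else "uni"
            cc = "bi" if cage_bi else "uni"
            comb = ce if ce == cc else "excluded"
        rows.append({
            "gene_id": g.gene_id,
            "active": is_active,
            "class_ensembl": ce,
            "class_cage": cc,
            "class_combined": comb,
            "sense_tags": (sense_tags or {}).get(g.gene_id, np.nan),
            "antisense_tags": (antisense_tags or {}).get(g.gene_id, np.nan),
            "has_upstream_alt_tss": is_active and g.gene_id not in no_alt,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def agreement(annotation: pd.DataFrame) -> float:
    """Percent of active genes on which the two annotation rules agree."""
    act = annotation[annotation["active"]]
    if len(act) == 0:
        return float("nan")
    return 100.0 * (act["class_ensembl"] == act["class_cage"]).mean()


def cross_sample_consistency(
    annotations: Sequence[pd.DataFrame],
) -> tuple[pd.Series, pd.Series]:
    """Activity histogram and directionality consistency across samples.

    Returns ``(histogram, labels)``: a count of genes by number of samples
    in which they were active (0..n_samples), and, for genes active in at
    least two samples, a label among uni/bi/mixed — uni or bi when the
    combined class is that value in every sample where the gene is active,
    mixed otherwise (disagreeing or excluded calls count as mixed).
    """
    if len(annotations) < 2:
        raise ValueError("need at least two annotation sets")
    universe = annotations[0].index
    for ann in annotations[1:]:
        if not universe.equals(ann.index):
            raise ValueError("annotation sets cover different gene universes")
    active = pd.concat([a["active"] for a in annotations], axis=1)
    n_active = active.sum(axis=1)
    histogram = n_active.value_counts().reindex(
        range(len(annotations) + 1), fill_value=0)

    classes = pd.concat([a["class_combined"] for a in annotations], axis=1)
    labels = {}
    for gid in universe[n_active >= 2]:
        seen = set(classes.loc[gid][active.loc[gid].to_numpy(bool)])
        if seen == {"uni"}:
            labels[gid] = "uni"
        elif seen == {"bi"}:
            labels[gid] = "bi"
        else:
            labels[gid] = "mixed"
    return histogram, pd.Series(labels, dtype=object)


def filter_no_upstream_alt_tss(
    genes: Sequence[GeneModel],
    clusters: Sequence[GenomicInterval],
    activity_distance: int = ACTIVITY_DISTANCE,
    upstream_max: int = BIDIRECTIONAL_DISTANCE,
) -> list[str]:
    """Gene IDs without a same-strand cluster 11..1000 bp upstream.

    The activity-defining cluster at the TSS (within ``activity_distance``)
    never disqualifies its own gene: only clusters whose nearest point lies
    strictly more than ``activity_distance`` and at most ``upstream_max`` bp
    upstream count as alternative TSS evidence.
    """
    idx = _cluster_index(clusters)
    out = []
    for g in genes:
        entry = idx.get((g.chrom, g.strand))
        disqualified = False
        if entry is not None:
            _, _, ivs = entry
            for iv in ivs:
                q = min(max(g.tss, iv.start), iv.end - 1)  # nearest base
                upstream = (g.tss - q) if g.strand == "+" else (q - g.tss)
                if activity_distance < upstream <= upstream_max:
                    disqualified = True
                    break
        if not disqualified:
            out.append(g.gene_id)
    return out
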
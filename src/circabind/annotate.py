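"""Relating binding sites to transcripts and conservation.

Coordinates are 0-based half-open internally; the GTF reader converts from
the 1-based closed convention at the boundary.  Signed TSS distances follow
the transcript orientation: negative = upstream of the TSS.  Sites are
points without orientation, so "downstream" control regions follow the
genome's + direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "nearest_tss",
    "categorize_site",
    "conservation_score",
    "expressed_filter",
    "assign_targets",
    "control_region",
    "read_gtf_transcripts",
    "read_bed12_transcripts",
    "read_bedgraph_track",
]

TRANSCRIPT_COLUMNS = ["id", "chrom", "strand", "tss", "tes", "biotype", "expression"]

CATEGORIES = ("promoter", "upstream", "gene", "downstream", "other")


def nearest_tss(
    site_chrom: str, site_pos: int, transcripts: pd.DataFrame
) -> tuple[pd.Series, int]:
    """Transcript with the closest TSS and the signed distance to it.

    Distance is signed in the transcript's orientation (negative =
    upstream of the TSS); ties in |distance| go to the smallest transcript
    id for determinism.
    """
    if transcripts.empty:
        raise ValueError("empty transcript annotation")
    cand = transcripts[transcripts["chrom"] == site_chrom]
    if cand.empty:
        raise ValueError(f"no transcripts on {site_chrom}")
    dist = (site_pos - cand["tss"]).abs()
    ranked = cand.assign(_d=dist).sort_values(["_d", "id"], kind="mergesort")
    best = ranked.iloc[0].drop("_d")
    signed = int(site_pos - best["tss"])
    if best["strand"] == "-":
        signed = -signed
    return best, signed


def categorize_site(signed_distance: int, transcript: pd.Series) -> str:
    """Positional category of a site relative to its assigned transcript.

    promoter: within ±2 kb of the TSS; upstream: -10 kb to -2 kb;
    gene: +2 kb to the polyadenylation site; downstream: polyadenylation
    site to +10 kb; other: none of these.  Evaluated in transcript
    orientation, with the signed TSS distance as the coordinate.
    """
    g = signed_distance
    gene_len = abs(int(transcript["tes"]) - int(transcript["tss"]))
    if -2000 <= g <= 2000:
        return "promoter"
    if -10000 <= g < -2000:
        return "upstream"
    if 2000 < g <= gene_len:
        return "gene"
    if gene_len < g <= gene_len + 10000:
        return "downstream"
    return "other"


def conservation_score(
    site_chrom: str, site_pos: int, track: dict[str, np.ndarray], halfwidth: int = 50
) -> float:
    """Maximum conservation in ±``halfwidth`` bp around the site.

    ``track`` maps chromosome to a dense per-base score array in [0, 1];
    positions outside the array are treated as score 0.
    """
    if site_chrom not in track:
        raise KeyError(f"unknown chromosome {site_chrom!r}")
    arr = np.asarray(track[site_chrom])
    lo = max(site_pos - halfwidth, 0)
    hi = min(site_pos + halfwidth + 1, arr.size)
    if hi <= lo:
        return 0.0
    return float(arr[lo:hi].max())


def expressed_filter(
    transcripts: pd.DataFrame, percentile: float = 50.0
) -> tuple[pd.DataFrame, float]:
    """Transcripts expressed strictly above the given percentile.

    Returns the expressed subset and the threshold used.  With all-equal
    expression the strict inequality yields an empty set.
    """
    if "expression" not in transcripts or transcripts["expression"].isna().all():
        raise ValueError("no expression data")
    threshold = float(np.percentile(transcripts["expression"].to_numpy(), percentile))
    return transcripts[transcripts["expression"] > threshold], threshold


def assign_targets(
    sites: pd.DataFrame,
    transcripts: pd.DataFrame,
    max_distance: int = 10_000,
    coding_only: bool = True,
) -> pd.DataFrame:
    """Map each site to the nearest (optionally protein-coding) transcript
    with |TSS distance| <= ``max_distance``.

    Returns the site table with ``target_id``, ``tss_distance`` and
    ``category`` columns (NaN / 'other' for unassigned sites).
    """
    pool = transcripts
    if coding_only:
        pool = transcripts[transcripts["biotype"] == "coding"]
    out = sites.copy()
    target_ids, distances, categories = [], [], []
    for _, row in sites.iterrows():
        try:
            best, signed = nearest_tss(row["chrom"], int(row["position"]), pool)
        except ValueError:
            best, signed = None, None
        if best is None or abs(signed) > max_distance:
            target_ids.append(None)
            distances.append(np.nan)
            categories.append(None)
        else:
            target_ids.append(best["id"])
            distances.append(signed)
            categories.append(categorize_site(signed, best))
    out["target_id"] = target_ids
    out["tss_distance"] = distances
    out["category"] = categories
    return out


def control_region(
    site_pos: int, width: int, chrom_length: int, offset: int = 500
) -> tuple[int, int] | None:
    """Half-open control window of ``width`` bp centered ``offset`` bp
    downstream (genome + direction) of the site; ``None`` when it exceeds
    the chromosome (the site is flagged by the caller)."""
    center = site_pos + offset
    lo = center - width // 2
    hi = lo + width
    if lo < 0 or hi > chrom_length:
        return None
    return lo, hi


# -- readers ----------------------------------------------------------------


def read_gtf_transcripts(path, expression: dict | None = None) -> pd.DataFrame:
    """Transcript records from GTF (1-based closed converted to 0-based).

    Uses ``transcript`` features; the TSS is the strand-aware 5' end.
    ``expression`` optionally maps transcript id to an expression level.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]) - 1, int(f[4]), f[6], f[8]
            attr = {}
            for part in attrs.strip().split(";"):
                part = part.strip()
                if not part:
                    continue
                key, _, val = part.partition(" ")
                attr[key] = val.strip('"')
            tid = attr.get("transcript_id", f"{chrom}:{start}")
            biotype = attr.get("transcript_biotype", attr.get("gene_biotype", "coding"))
            if biotype in ("protein_coding", "coding"):
                biotype = "coding"
            elif biotype == "miRNA":
                biotype = "miRNA"
            else:
                biotype = "other ncRNA"
            tss, tes = (start, end) if strand == "+" else (end - 1, start)
            rows.append(
                {
                    "id": tid,
                    "chrom": chrom,
                    "strand": strand,
                    "tss": tss,
                    "tes": tes,
                    "biotype": biotype,
                    "expression": (expression or {}).get(tid, np.nan),
                }
            )
    return pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS)


def read_bed12_transcripts(path, expression: dict | None = None) -> pd.DataFrame:
    """Transcript records from BED12 (already 0-based half-open)."""
    bed = pd.read_csv(path, sep="\t", header=None)
    rows = []
    for _, r in bed.iterrows():
        chrom, start, end, name, strand = r[0], int(r[1]), int(r[2]), str(r[3]), r[5]
        tss, tes = (start, end) if strand == "+" else (end - 1, start)
        rows.append(
            {
                "id": name,
                "chrom": chrom,
                "strand": strand,
                "tss": tss,
                "tes": tes,
                "biotype": "coding",
                "expression": (expression or {}).get(name, np.nan),
            }
        )
    return pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS)


def read_bedgraph_track(path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Dense per-base conservation arrays from a bedGraph file."""
    track = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    bg = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "score"])
    for _, r in bg.iterrows():
        if r["chrom"] in track:
            track[r["chrom"]][int(r["start"]) : int(r["end"])] = float(r["score"])
    return track
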
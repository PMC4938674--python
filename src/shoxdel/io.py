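"""Readers and writers for the pipeline's interchange formats.

Formats are deliberately plain: samtools-depth-style TSV for per-position
depth (1-based positions), a long TSV dialect or minimal VCF 4.2 (per-sample
AD) for SNP read counts, CSV for droplet counts, JSON for the region model,
TSV/bedGraph/BED for windowed results and calls.  Coordinates are 0-based
half-open internally; 1-based conversion happens only at the depth-TSV and
VCF boundaries.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .region import RegionModel, RepeatRun
from .segments import DeletionCall
from .simulate import DepthTrack

# -- depth ------------------------------------------------------------------


def write_depth_tsv(path, tracks: Mapping[str, DepthTrack], chrom: str = "region") -> None:
    """samtools-depth-style TSV: chrom, 1-based pos, one depth column per sample.

    A ``#`` header line carries the sample ids; a second header line records
    each sample's genome background mean depth (needed for normalization and
    not representable in the bare samtools format).
    """
    ids = list(tracks)
    lengths = {len(t) for t in tracks.values()}
    if len(lengths) != 1:
        raise ValueError("tracks must share one region length")
    n = lengths.pop()
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\t" + "\t".join(ids) + "\n")
        fh.write("#background_mean\t.\t" + "\t".join(str(tracks[i].background_mean) for i in ids) + "\n")
        mat = np.column_stack([tracks[i].depth for i in ids])
        for pos in range(n):
            fh.write(f"{chrom}\t{pos + 1}\t" + "\t".join(map(str, mat[pos])) + "\n")


def read_depth_tsv(path) -> dict[str, DepthTrack]:
    """Read a depth TSV written by :func:`write_depth_tsv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        bg_line = fh.readline().rstrip("\n").split("\t")
    if not header[0].startswith("#") or bg_line[0] != "#background_mean":
        raise ValueError("missing depth TSV header lines")
    ids = header[2:]
    backgrounds = [float(x) for x in bg_line[2:]]
    mat = pd.read_csv(path, sep="\t", comment="#", header=None).to_numpy()
    depths = mat[:, 2:].astype(np.int64)
    return {
        sid: DepthTrack(
            sample_id=sid,
            depth=depths[:, k],
            softclip=np.zeros(len(depths), dtype=np.int64),
            background_mean=bg,
        )
        for k, (sid, bg) in enumerate(zip(ids, backgrounds))
    }


def write_softclip_tsv(path, tracks: Mapping[str, DepthTrack], chrom: str = "region") -> None:
    """Companion TSV of per-position soft-clip counts, same layout as depth."""
    ids = list(tracks)
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\t" + "\t".join(ids) + "\n")
        mat = np.column_stack([tracks[i].softclip for i in ids])
        for pos in range(mat.shape[0]):
            fh.write(f"{chrom}\t{pos + 1}\t" + "\t".join(map(str, mat[pos])) + "\n")


def read_softclip_tsv(path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")[2:]
    mat = pd.read_csv(path, sep="\t", comment="#", header=None).to_numpy()
    return {sid: mat[:, 2 + k].astype(np.int64) for k, sid in enumerate(ids)}


# -- SNP counts -------------------------------------------------------------

SNP_TSV_COLUMNS = ["position", "sample_id", "ref_count", "alt_count"]


def write_snp_tsv(path, table: pd.DataFrame) -> None:
    table[SNP_TSV_COLUMNS].to_csv(path, sep="\t", index=False)


def read_snp_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(SNP_TSV_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"SNP TSV missing columns: {sorted(missing)}")
    return table


def write_snp_vcf(path, table: pd.DataFrame, chrom: str = "region", region_length: int | None = None) -> None:
    """Write SNP read counts as a minimal VCF 4.2 with per-sample AD.

    Simulated sites carry placeholder REF=A / ALT=C alleles; the information
    content is the per-sample allelic depth.  Positions convert to 1-based.
    """
    samples = list(pd.unique(table["sample_id"]))
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    length = region_length or int(table["position"].max()) + 1
    header.add_line(f"##contig=<ID={chrom},length={length}>")
    for s in samples:
        header.add_sample(s)
    wide_ref = table.pivot_table(index="position", columns="sample_id", values="ref_count", aggfunc="sum").fillna(0)
    wide_alt = table.pivot_table(index="position", columns="sample_id", values="alt_count", aggfunc="sum").fillna(0)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos in wide_ref.index:
            rec = vcf.new_record(contig=chrom, start=int(pos), stop=int(pos) + 1, alleles=("A", "C"))
            for s in samples:
                rec.samples[s]["AD"] = (int(wide_ref.loc[pos, s]), int(wide_alt.loc[pos, s]))
            vcf.write(rec)


def read_snp_vcf(path) -> pd.DataFrame:
    """Read a VCF with per-sample AD back into the long count-table dialect."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for s, call in rec.samples.items():
                ad = call.get("AD")
                ref, alt = (ad[0] or 0, ad[1] or 0) if ad else (0, 0)
                rows.append(
                    {"position": rec.start, "sample_id": s, "ref_count": int(ref), "alt_count": int(alt)}
                )
    return pd.DataFrame(rows, columns=SNP_TSV_COLUMNS)


# -- droplets ---------------------------------------------------------------

DROPLET_COLUMNS = ["sample_id", "assay_id", "assay_target", "total_droplets", "positive_droplets"]


def write_droplet_csv(path, droplets: pd.DataFrame) -> None:
    droplets[DROPLET_COLUMNS].to_csv(path, index=False)


def read_droplet_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(DROPLET_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"droplet CSV missing columns: {sorted(missing)}")
    return table


# -- region model -----------------------------------------------------------


def write_region_json(path, model: RegionModel) -> None:
    payload = {
        "region_length": model.region_length,
        "del1": list(model.del1),
        "del2": list(model.del2),
        "snp_positions": [int(p) for p in model.snp_positions],
        "snp_alt_freqs": [float(f) for f in model.snp_alt_freqs],
        "founder_alt": [int(a) for a in model.founder_alt],
        "repeat_runs": [dataclasses.asdict(r) for r in model.repeat_runs],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_region_json(path) -> RegionModel:
    payload = json.loads(Path(path).read_text())
    return RegionModel(
        region_length=payload["region_length"],
        del1=tuple(payload["del1"]),
        del2=tuple(payload["del2"]),
        snp_positions=np.asarray(payload["snp_positions"], dtype=np.int64),
        snp_alt_freqs=np.asarray(payload["snp_alt_freqs"], dtype=float),
        founder_alt=np.asarray(payload["founder_alt"], dtype=np.int8),
        repeat_runs=tuple(RepeatRun(**r) for r in payload["repeat_runs"]),
    )


# -- windows, calls, screen -------------------------------------------------


def write_window_tsv(path, window_table: pd.DataFrame) -> None:
    window_table.to_csv(path, sep="\t", index=False)


def write_bedgraph(path, window_table: pd.DataFrame, column: str, chrom: str = "region") -> None:
    sub = window_table[["start", "end", column]].copy()
    sub.insert(0, "chrom", chrom)
    sub.to_csv(path, sep="\t", index=False, header=False)


def write_calls_bed(path, calls: Sequence[DeletionCall], chrom: str = "region") -> None:
    """BED6 of deletion calls; name = sample:state, score = n_windows."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{chrom}\t{c.start}\t{c.end}\t{c.sample_id}:{c.state}\t{c.n_windows}\t.\n")


def write_screen_bed(path, results: pd.DataFrame, chrom: str = "region") -> None:
    """BED of screen-passing SNP sites."""
    passing = results[results["passes"]]
    with open(path, "w") as fh:
        for pos in passing["position"]:
            fh.write(f"{chrom}\t{int(pos)}\t{int(pos) + 1}\n")
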
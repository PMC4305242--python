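"""File formats: VCF (pysam write / cyvcf2 read), FASTA, TSV and BED tables.

One VCF per colony holds every sample: the queen (diploid genotypes), the
drones (haploid calls written as diploid genotypes -- a het call in a
drone is the multi-copy artifact the filters look for) and the workers
(diploid). A two-column manifest TSV assigns each sample its role
(queen/drone/worker).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF
from pyfaidx import Fasta

from ._alleles import HET, MISSING, decode_base, encode_base
from .simulate import Colony

__all__ = [
    "write_reference_fasta",
    "read_reference_fasta",
    "write_colony_vcf",
    "read_colony_vcf",
    "write_manifest",
    "read_manifest",
    "write_truth_tsv",
    "write_bed",
    "write_events_tsv",
    "write_discard_report",
]


def write_reference_fasta(reference: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path), rebuild=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_manifest(colony: Colony, path: str | Path) -> None:
    rows = [("queen", "queen")]
    rows += [(n, "drone") for n in colony.drone_names]
    rows += [(n, "worker") for n in colony.worker_names]
    pd.DataFrame(rows, columns=["sample", "role"]).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "role"} <= set(df.columns):
        raise ValueError("manifest needs 'sample' and 'role' columns")
    return df


def write_colony_vcf(colony: Colony, path: str | Path) -> None:
    """Write queen + drone + worker genotypes to a plain-text VCF."""
    header = pysam.VariantHeader()
    for chrom, length in zip(colony.queen.chrom_names, colony.queen.chrom_lengths):
        header.contigs.add(chrom, length=length)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = ["queen", *colony.drone_names, *colony.worker_names]
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom in colony.queen.chrom_names:
            pos = colony.queen.positions[chrom]
            alleles = colony.queen.alleles[chrom]
            qual = colony.queen.quality[chrom]
            drones = colony.drone_alleles[chrom]
            workers = colony.worker_alleles[chrom]
            for i in range(len(pos)):
                site_alleles = [int(alleles[i, 0]), int(alleles[i, 1])]
                def allele_index(code: int) -> int | None:
                    if code == MISSING:
                        return None
                    if code not in site_alleles:
                        site_alleles.append(int(code))
                    return site_alleles.index(int(code))

                gts: list[tuple] = [(0, 1)]  # queen
                for d in range(drones.shape[0]):
                    c = int(drones[d, i])
                    if c == HET:
                        gts.append((0, 1))
                    elif c == MISSING:
                        gts.append((None, None))
                    else:
                        j = allele_index(c)
                        gts.append((j, j))
                for w in range(workers.shape[0]):
                    a = allele_index(int(workers[w, i, 0]))
                    b = allele_index(int(workers[w, i, 1]))
                    gts.append((a, b))
                rec = out.new_record(
                    contig=chrom,
                    start=int(pos[i]) - 1,
                    alleles=tuple(decode_base(c) for c in site_alleles),
                    qual=float(qual[i]),
                )
                for s, gt in zip(samples, gts):
                    rec.samples[s]["GT"] = gt
                out.write(rec)


def read_colony_vcf(
    vcf_path: str | Path, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, dict[str, np.ndarray]]]:
    """Read a colony VCF back into tabular form.

    Returns (queen site table, genotype dict): the table has chrom, pos,
    allele_a, allele_b, qual for queen-called sites; the dict maps role ->
    chrom -> coded arrays (drones: (n, sites) with HET/MISSING sentinels;
    workers: (n, sites, 2)).
    """
    roles = dict(zip(manifest["sample"], manifest["role"]))
    vcf = VCF(str(vcf_path), gts012=False)
    samples = vcf.samples
    queen_idx = [i for i, s in enumerate(samples) if roles.get(s) == "queen"]
    drone_idx = [i for i, s in enumerate(samples) if roles.get(s) == "drone"]
    worker_idx = [i for i, s in enumerate(samples) if roles.get(s) == "worker"]
    if len(queen_idx) != 1:
        raise ValueError("manifest must designate exactly one queen")
    q = queen_idx[0]

    rows = []
    drone_cols: dict[str, list[np.ndarray]] = {}
    worker_cols: dict[str, list[np.ndarray]] = {}
    for rec in vcf:
        alleles = [rec.REF, *rec.ALT]
        codes = [encode_base(a) if len(a) == 1 and a in "ACGT" else MISSING for a in alleles]
        gts = rec.genotype.array()  # (n_samples, ploidy+1)
        qa, qb = gts[q, 0], gts[q, 1]
        if qa < 0 or qb < 0:
            continue
        rows.append(
            (
                rec.CHROM, rec.POS, alleles[qa], alleles[qb],
                rec.QUAL if rec.QUAL is not None else 0.0,
            )
        )
        dcol = np.empty(len(drone_idx), dtype=np.int8)
        for k, d in enumerate(drone_idx):
            a, b = gts[d, 0], gts[d, 1]
            if a < 0 or b < 0:
                dcol[k] = MISSING
            elif a != b:
                dcol[k] = HET
            else:
                dcol[k] = codes[a]
        wcol = np.empty((len(worker_idx), 2), dtype=np.int8)
        for k, w in enumerate(worker_idx):
            a, b = gts[w, 0], gts[w, 1]
            wcol[k, 0] = codes[a] if a >= 0 else MISSING
            wcol[k, 1] = codes[b] if b >= 0 else MISSING
        drone_cols.setdefault(rec.CHROM, []).append(dcol)
        worker_cols.setdefault(rec.CHROM, []).append(wcol)

    queen_table = pd.DataFrame(
        rows, columns=["chrom", "pos", "allele_a", "allele_b", "qual"]
    )
    genotypes = {
        "drone": {c: np.stack(v, axis=1) for c, v in drone_cols.items()},
        "worker": {c: np.stack(v, axis=1) for c, v in worker_cols.items()},
    }
    return queen_table, genotypes


def write_truth_tsv(colony: Colony, path: str | Path) -> None:
    colony.truth.events.to_csv(path, sep="\t", index=False)


def write_bed(df: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    """Write chrom/start/end (1-based inclusive in memory) as 0-based BED."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
        }
    )
    if name_col and name_col in df:
        out["name"] = df[name_col]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def write_discard_report(report, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2) + "\n")
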
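"""File-format helpers: FASTA, GFF3, BED, feature-report TSV.

FASTA goes through Biopython; GFF3 here is the minimal dialect needed to
carry a provirus feature map (1-based inclusive on disk, converted to the
package's 0-based half-open convention in memory).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

from Bio import SeqIO

from .annotate import ProvirusCall, RefAnnotation
from .features import GENES


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


_GFF_TYPES = {"ltr5": "long_terminal_repeat", "ltr3": "long_terminal_repeat",
              "pbs": "primer_binding_site", "ppt": "polypurine_tract",
              "tsd": "target_site_duplication"}


def write_reference_gff3(features: dict, seqid: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, (start, end) in sorted(features.items(),
                                         key=lambda kv: kv[1]):
            ftype = _GFF_TYPES.get(name, "gene" if name in GENES
                                   else "region")
            fh.write(f"{seqid}\tervclock\t{ftype}\t{start + 1}\t{end}\t."
                     f"\t+\t.\tID={name}\n")


def read_reference_gff3(path) -> dict:
    features = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError("malformed GFF3 row")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if kv)
            name = attrs.get("ID") or attrs.get("Name")
            features[name] = (int(cols[3]) - 1, int(cols[4]))
    return features


def load_reference(fasta_path, gff_path) -> RefAnnotation:
    recs = read_fasta(fasta_path)
    if len(recs) != 1:
        raise ValueError("reference FASTA must contain exactly one record")
    seq = next(iter(recs.values()))
    features = read_reference_gff3(gff_path)
    for need in ("ltr5", "ltr3", *GENES):
        if need not in features:
            raise ValueError(f"reference annotation lacks {need!r}")
    return RefAnnotation(seq=seq, features=features)


def write_calls_gff3(calls: list[ProvirusCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for call in calls:
            base = call.locus_start
            sid = call.contig or call.locus_id

            def row(name, interval, extra=""):
                ftype = _GFF_TYPES.get(name,
                                       "gene" if name in GENES else "region")
                a, b = interval
                attrs = f"ID={call.locus_id}.{name}"
                if extra:
                    attrs += ";" + extra
                fh.write(f"{sid}\tervclock\t{ftype}\t{base + a + 1}"
                         f"\t{base + b}\t.\t{call.strand}\t.\t{attrs}\n")

            row("provirus", call.provirus,
                f"subgroup={call.subgroup}")
            row("ltr5", call.ltr5)
            row("ltr3", call.ltr3)
            for gene in GENES:
                if call.genes.get(gene):
                    row(gene, call.genes[gene])


def calls_report_rows(calls: list[ProvirusCall]) -> list[dict]:
    rows = []
    for c in calls:
        row = {
            "locus_id": c.locus_id, "contig": c.contig,
            "start": c.locus_start + c.provirus[0],
            "end": c.locus_start + c.provirus[1], "strand": c.strand,
            "subgroup": c.subgroup, "tsd": c.tsd or "",
            "ltr5": f"{c.ltr5[0]}-{c.ltr5[1]}",
            "ltr3": f"{c.ltr3[0]}-{c.ltr3[1]}",
            "mapping_identity": round(c.mapping_identity, 2),
            "gag_late_domain_1": c.motifs.gag_late_domain_1,
            "gag_late_domain_2": c.motifs.gag_late_domain_2,
            "env_cettg": c.motifs.env_cettg,
            "deletions": ";".join(
                f"{s.gene}:{s.expected or 'other'}:{s.observed}"
                for s in c.deletions),
            "flags": ";".join(c.flags),
        }
        for gene in GENES:
            row[f"{gene}_status"] = c.orfs.status.get(gene, "absent")
            stops = c.orfs.stop_positions.get(gene, [])
            row[f"{gene}_stops"] = ";".join(map(str, stops))
        rows.append(row)
    return rows


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_paths(paths) -> dict:
    return {Path(p).name: sha256_file(p) for p in paths}
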
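"""File formats: minimal VCFv4.2, headered CSV tables, truth/config files.

Genotypes travel as VCF (GT plus optional DP/GQ FORMAT fields, read with
cyvcf2); population maps, coordinates, environmental tables and mitotypes
as headered CSV; the synthetic-truth record as JSON; generator configs as
plain ``key: value`` text.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .demography import IMParams


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2 with GT only (REF=A, ALT=G placeholders).

    Fragment labels, when present, are stored in the INFO field (``FRAG=``)
    so a round-trip preserves the block-bootstrap units.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=FRAG,Number=1,Type=String,Description="Fragment label">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.individual_ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        frags = G.fragments if G.fragments is not None else [None] * G.n_loci
        for j in range(G.n_loci):
            info = f"FRAG={frags[j]}" if frags[j] is not None else "."
            cells = "\t".join(gt_map[int(G.calls[i, j])]
                              for i in range(G.n_individuals))
            fh.write(f"1\t{j + 1}\t{G.locus_ids[j]}\tA\tG\t.\t.\t{info}\tGT\t{cells}\n")


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, int]:
    """Read a VCF into a GenotypeMatrix; returns (matrix, n_multiallelic_skipped).

    Only biallelic SNP records are kept; missing GT becomes MISSING; DP and
    GQ FORMAT fields are loaded into the quality layers when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls, depths, gqs, ids, frags = [], [], [], [], []
    skipped = 0
    has_dp = has_gq = False
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                row[i] = a + b
        calls.append(row)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        frag = var.INFO.get("FRAG")
        frags.append(frag)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        try:
            gq = var.format("GQ")
        except KeyError:
            gq = None
        if dp is not None:
            has_dp = True
            depths.append(dp.ravel())
        else:
            depths.append(np.full(len(samples), -1))
        if gq is not None:
            has_gq = True
            gqs.append(gq.ravel())
        else:
            gqs.append(np.full(len(samples), -1))
    if not calls:
        raise ValueError(f"no usable biallelic records in {path}")
    fragments = (np.array([f if f is not None else "" for f in frags])
                 if any(f is not None for f in frags) else None)
    G = GenotypeMatrix(
        calls=np.array(calls, dtype=np.int8).T,
        individual_ids=samples,
        locus_ids=ids,
        depth=np.array(depths).T if has_dp else None,
        gq=np.array(gqs).T if has_gq else None,
        fragments=fragments,
    )
    return G, skipped


def write_popmap(popmap: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"individual": list(popmap), "population": list(popmap.values())}
    ).to_csv(path, index=False)


def read_popmap(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "population") -> None:
    df.to_csv(path, index_label=index_label)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_truth(truth: Mapping, path: str | Path) -> None:
    out = {}
    for k, v in truth.items():
        if isinstance(v, IMParams):
            d = dataclasses.asdict(v)
            d["migrants"] = np.asarray(d["migrants"]).tolist()
            out[k] = d
        elif isinstance(v, np.ndarray):
            out[k] = v.tolist()
        else:
            out[k] = v
    Path(path).write_text(json.dumps(out, indent=2, default=str) + "\n")


def read_truth(path: str | Path) -> dict:
    truth = json.loads(Path(path).read_text())
    if "im_params" in truth and isinstance(truth["im_params"], dict):
        d = dict(truth["im_params"])
        d["migrants"] = np.asarray(d["migrants"], dtype=float)
        truth["im_params"] = IMParams(**d)
    return truth


def write_config_text(config, path: str | Path) -> None:
    """Serialize a (dataclass) config as plain ``key: value`` lines."""
    lines = []
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if dataclasses.is_dataclass(v):
            v = dataclasses.asdict(v)
        lines.append(f"{f.name}: {v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_bundle(bundle, outdir: str | Path) -> None:
    """Write a synthetic bundle to a directory in the interchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(bundle.genotypes, outdir / "genotypes.vcf")
    write_popmap(bundle.popmap, outdir / "popmap.csv")
    write_table(bundle.coords, outdir / "coords.csv")
    write_table(bundle.env, outdir / "env.csv")
    pd.DataFrame({"individual": list(bundle.mitotypes),
                  "mitotype": list(bundle.mitotypes.values())}
                 ).to_csv(outdir / "mitotypes.csv", index=False)
    write_truth(bundle.truth, outdir / "truth.json")


def load_bundle(outdir: str | Path):
    from .synthdata import SynthBundle

    outdir = Path(outdir)
    G, skipped = read_vcf(outdir / "genotypes.vcf")
    if skipped:
        warnings.warn(f"skipped {skipped} multiallelic records")
    mito = pd.read_csv(outdir / "mitotypes.csv")
    return SynthBundle(
        genotypes=G,
        popmap=read_popmap(outdir / "popmap.csv"),
        coords=read_table(outdir / "coords.csv"),
        env=read_table(outdir / "env.csv"),
        mitotypes=dict(zip(mito.iloc[:, 0].astype(str), mito.iloc[:, 1].astype(str))),
        truth=read_truth(outdir / "truth.json"),
    )
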
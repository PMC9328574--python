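"""Deterministic on-disk fixtures for I/O and pipeline tests.

Writes a small simulated cohort in every supported input format (PLINK triple,
VCF, BED and GFF3 region annotations, phenotype TSV) together with a YAML copy
of the generating simulation spec, so the phenotype can be regenerated exactly
from the files alone.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .io import write_phenotype, write_plink, write_vcf
from .simulate import EffectScales, GeneSpec, SimulatedDataset, SimulationSpec, simulate_dataset

__all__ = ["make_fixtures", "spec_to_dict", "spec_from_dict", "default_fixture_spec"]


def spec_to_dict(spec: SimulationSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["genes"] = [dataclasses.asdict(g) for g in spec.genes]
    d["effect_scales"] = dataclasses.asdict(spec.effect_scales)
    for key in ("switches", "causal_fractions", "maf_range"):
        d[key] = list(d[key])
    return d


def spec_from_dict(d: dict) -> SimulationSpec:
    d = dict(d)
    d["genes"] = tuple(GeneSpec(**g) for g in d["genes"])
    d["effect_scales"] = EffectScales(**d["effect_scales"])
    for key in ("switches", "causal_fractions", "maf_range"):
        d[key] = tuple(d[key])
    return SimulationSpec(**d)


def default_fixture_spec(seed: int) -> SimulationSpec:
    return SimulationSpec(
        n=30,
        genes=(
            GeneSpec("fixA", 5, "linear90"),
            GeneSpec("fixB", 4, "null"),
            GeneSpec("fixC", 6, "null"),
        ),
        signal_fraction=0.3,
        seed=seed,
    )


def make_fixtures(out_dir: str | Path, seed: int = 0, spec: SimulationSpec | None = None) -> dict:
    """Write the fixture file set; returns a path map. Pure function of ``seed``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or default_fixture_spec(seed)
    ds: SimulatedDataset = simulate_dataset(spec)

    paths = {
        "plink": out / "fixture",
        "vcf": out / "fixture.vcf",
        "bed_regions": out / "regions.bed",
        "gff3_regions": out / "regions.gff3",
        "phenotype": out / "phenotype.tsv",
        "spec": out / "simspec.yaml",
    }
    write_plink(ds.genotypes, paths["plink"])
    write_vcf(ds.genotypes, paths["vcf"])
    write_phenotype(ds.phenotype, ds.genotypes.samples, paths["phenotype"])

    with open(paths["bed_regions"], "w") as bed, open(paths["gff3_regions"], "w") as gff:
        gff.write("##gff-version 3\n")
        for region in ds.regions:
            pos = [ds.genotypes.variants[j].pos for j in region.variant_indices]
            chrom = ds.genotypes.variants[region.variant_indices[0]].chrom
            start, end = min(pos), max(pos)
            bed.write(f"{chrom}\t{start - 1}\t{end}\t{region.gene_id}\n")
            gff.write(
                f"{chrom}\tdnnprs\tgene\t{start}\t{end}\t.\t+\t.\tID={region.gene_id}\n"
            )
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}
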
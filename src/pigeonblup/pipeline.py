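"""End-to-end orchestration: encode -> fit five traits -> DEBV -> associate.

:func:`run_pipeline` consumes the pedigree/phenotype/genotype CSV dialects,
runs the liability-threshold Gibbs sampler per race trait, standardizes
EBVs into DEBV, summarizes the microsatellite locus, tests the carrier
association per trait, and writes every output plus a JSON run manifest
(config snapshot, input checksums, seeds, stage timings) sufficient to
reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__, ebv as ebv_mod, io as pio, microsat
from .association import associate_all_traits, group_distribution_summary
from .gibbs import GibbsConfig, ThresholdModel
from .phenotypes import DEFAULT_THRESHOLDS_KM, encode_race_traits

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: dict[str, str]
    seed: int
    timings_s: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(
    pedigree_csv: Path,
    phenotype_csv: Path,
    genotype_csv: Path,
    out_dir: Path,
    gibbs_config: Optional[GibbsConfig] = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS_KM,
    threshold_comparison: str = "ge",
    target_allele: str = "S",
    debv_reference: str = "all_pedigree",
    seed: int = 0,
) -> RunManifest:
    """Run the full inference chain; returns the manifest (also written).

    Per-trait seeds are derived deterministically from ``seed`` so the five
    Gibbs chains are independent but the whole run is reproducible.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = gibbs_config or GibbsConfig(seed=seed)
    manifest = RunManifest(
        version=__version__,
        config={
            "gibbs": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
            "thresholds": list(thresholds),
            "threshold_comparison": threshold_comparison,
            "target_allele": target_allele,
            "debv_reference": debv_reference,
        },
        input_checksums={
            "pedigree": _sha256(Path(pedigree_csv)),
            "phenotypes": _sha256(Path(phenotype_csv)),
            "genotypes": _sha256(Path(genotype_csv)),
        },
        seed=seed,
    )

    t0 = time.perf_counter()
    pedigree = pio.read_pedigree_csv(pedigree_csv)
    distances = pio.read_phenotype_csv(phenotype_csv)
    genotypes = pio.read_genotype_csv(genotype_csv)
    missing = [r.animal_id for r in distances if r.animal_id not in pedigree.index]
    if missing:
        raise ValueError(
            f"{len(missing)} phenotyped animals absent from pedigree: {missing[:10]}"
        )
    manifest.timings_s["load"] = round(time.perf_counter() - t0, 3)

    # Stage 1: binary race-trait coding
    t0 = time.perf_counter()
    traits = encode_race_traits(distances, thresholds, threshold_comparison)
    trait_path = out_dir / "race_traits.tsv"
    pio.write_tsv(traits.to_frame(), trait_path)
    manifest.outputs["race_traits"] = str(trait_path)
    manifest.timings_s["encode"] = round(time.perf_counter() - t0, 3)

    # Stage 2: threshold-model Gibbs per trait
    t0 = time.perf_counter()
    sex = [pedigree.records[pedigree.index[a]].sex for a in traits.ids]
    model = ThresholdModel(pedigree, traits.ids, sex)
    samples_by_trait = {}
    h2_rows = []
    ss = np.random.SeedSequence(seed)
    trait_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(traits.trait_names))]
    for k, name in enumerate(traits.trait_names):
        cfg_k = GibbsConfig(
            **{
                **{f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
                "seed": trait_seeds[k],
            }
        )
        samples = model.fit(traits.Y[:, k], cfg_k, trait=name)
        samples_by_trait[name] = samples
        h2_rows.append(samples.summary())
        pio.write_posterior_tsv(samples, out_dir / f"posterior_{name}.tsv")
        manifest.outputs[f"posterior_{name}"] = str(out_dir / f"posterior_{name}.tsv")
    h2_path = out_dir / "heritability.tsv"
    pio.write_tsv(pd.DataFrame(h2_rows), h2_path)
    manifest.outputs["heritability"] = str(h2_path)
    manifest.timings_s["fit"] = round(time.perf_counter() - t0, 3)

    # Stage 3: EBV posterior means and DEBV standardization
    t0 = time.perf_counter()
    genotyped_ids = [g.animal_id for g in genotypes if not g.is_missing]
    table = ebv_mod.ebv_table(
        samples_by_trait,
        reference=debv_reference,
        phenotyped_ids=traits.ids,
        genotyped_ids=genotyped_ids,
    )
    ebv_path = out_dir / "ebv_debv.tsv"
    pio.write_tsv(table, ebv_path)
    manifest.outputs["ebv_debv"] = str(ebv_path)
    manifest.timings_s["standardize"] = round(time.perf_counter() - t0, 3)

    # Stage 4: genotype summary
    t0 = time.perf_counter()
    summary = microsat.summarize(genotypes, target_allele=target_allele)
    geno_path = out_dir / "genotype_summary.tsv"
    pio.write_tsv(summary.to_frame(), geno_path)
    manifest.outputs["genotype_summary"] = str(geno_path)
    if not summary.is_monomorphic:
        hwe = summary.hwe(method="chi2")
        (out_dir / "hwe.json").write_text(
            json.dumps(
                {
                    "method": hwe.method,
                    "statistic": hwe.statistic,
                    "df": hwe.df,
                    "p_value": hwe.p_value,
                    "min_expected": hwe.min_expected,
                },
                indent=2,
            )
            + "\n"
        )
        manifest.outputs["hwe"] = str(out_dir / "hwe.json")
    manifest.timings_s["summarize_genotypes"] = round(time.perf_counter() - t0, 3)

    # Stage 5: association of carrier group with DEBV
    t0 = time.perf_counter()
    carriers = pd.Series(
        {
            g.animal_id: microsat.classify_carrier(g, target_allele)
            for g in genotypes
            if not g.is_missing
        }
    )
    report = associate_all_traits(table, carriers)
    assoc_path = out_dir / "association.tsv"
    pio.write_tsv(report, assoc_path)
    manifest.outputs["association"] = str(assoc_path)
    dist_path = out_dir / "group_debv_summary.tsv"
    pio.write_tsv(group_distribution_summary(table, carriers), dist_path)
    manifest.outputs["group_debv_summary"] = str(dist_path)
    manifest.timings_s["associate"] = round(time.perf_counter() - t0, 3)

    manifest.write(out_dir / "manifest.json")
    manifest.outputs["manifest"] = str(out_dir / "manifest.json")
    return manifest
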
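"""End-to-end orchestration: data -> networks -> topology/stability ->
comparisons -> reports, reproducibly from one config.

A run covers two soils x four treatment levels (control CK plus three
doses L/M/H), one network per group, then compares each dose network
against its soil's control.  All randomness flows from seeds recorded in
the config, so re-running a config reproduces every numeric output.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .containers import FUNCTION_CATEGORIES, TREATMENT_LEVELS, AbundanceTable
from .comparison import (
    bray_curtis,
    compare_networks,
    euclidean_profile_distance,
    mantel,
)
from .inference import infer_network
from .stability import robustness_curve, robustness_scalar, vulnerability
from .synthetic import (
    SyntheticDesign,
    generate_community,
    generate_function_table,
    generate_taxonomy,
)
from .topology import (
    classify_roles,
    detect_modules,
    keystone_overlap,
    node_phylum_composition,
    topological_indices,
    zipi,
)

DOSE_LEVELS = ("L", "M", "H")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either ``synthetic`` holds generator parameters (two synthetic soils
    are derived from ``seed`` and ``seed + 1``) or ``inputs`` points at
    abundance/metadata/taxonomy files whose metadata carries ``soil`` and
    ``treatment`` columns.  Everything else is analysis parameters with
    the conventional defaults: |r| >= 0.9 edges, Louvain modules, 100
    robustness repetitions, 999 permutations, Bonferroni at alpha 0.05
    on modules of at least 5 nodes.
    """

    synthetic: dict | None = None
    inputs: dict | None = None
    threshold: float = 0.9
    mode: str = "absolute"
    min_prevalence: float = 0.0
    min_mean_abundance: float = 0.0
    module_algorithm: str = "louvain"
    module_seed: int = 0
    robustness_repetitions: int = 100
    robustness_seed: int = 0
    robustness_at: float = 0.5
    n_permutations: int = 999
    permutation_seed: int = 0
    alpha: float = 0.05
    min_module_size: int = 5
    function_coupling: float = 0.8
    dissimilarity_variant: str = "jaccard_links"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of synthetic/inputs must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SoilData:
    """Everything one soil contributes: a table per treatment plus
    taxonomy, and (synthetic runs) ground truth and function tables."""

    tables: dict = field(default_factory=dict)      # treatment -> AbundanceTable
    taxonomy: dict = field(default_factory=dict)
    truths: dict = field(default_factory=dict)      # treatment -> GroundTruth
    functions: dict = field(default_factory=dict)   # treatment -> FunctionTable


def load_soils(config: RunConfig) -> dict:
    """Materialise per-soil data from the config (synthetic or files)."""
    soils: dict[str, SoilData] = {}
    if config.synthetic is not None:
        params = dict(config.synthetic)
        n_soils = int(params.pop("n_soils", 2))
        base_seed = int(params.pop("seed", 0))
        for index in range(n_soils):
            design = SyntheticDesign(seed=base_seed + index, **params)
            soil = SoilData(taxonomy=generate_taxonomy(design))
            for level in TREATMENT_LEVELS:
                table, truth = generate_community(design, level)
                soil.tables[level] = table
                soil.truths[level] = truth
                soil.functions[level] = generate_function_table(
                    table, truth, config.function_coupling,
                    seed=design.seed + 17,
                )
            soils[f"soil{index + 1}"] = soil
    else:
        table = cio.read_abundance_table(
            config.inputs["abundance"], config.inputs["metadata"]
        )
        taxonomy = cio.read_taxonomy(config.inputs["taxonomy"])
        functions = (
            cio.read_function_table(config.inputs["functions"])
            if config.inputs.get("functions")
            else None
        )
        for soil_name, soil_meta in table.metadata.groupby("soil"):
            soil = SoilData(taxonomy=taxonomy)
            for level, level_meta in soil_meta.groupby("treatment"):
                group = table.subset_samples(level_meta.index)
                soil.tables[level] = group
                if functions is not None:
                    sub = functions.values[list(level_meta.index)]
                    soil.functions[level] = type(functions)(sub)
            soils[str(soil_name)] = soil
    return soils


def analyze_group(table: AbundanceTable, config: RunConfig, provenance: dict):
    """Network + per-network analyses for one soil x treatment group."""
    net = infer_network(
        table,
        threshold=config.threshold,
        mode=config.mode,
        min_prevalence=config.min_prevalence,
        min_mean_abundance=config.min_mean_abundance,
        provenance=provenance,
    )
    indices = topological_indices(net)
    partition = detect_modules(net, config.module_algorithm, config.module_seed)
    roles = classify_roles(zipi(net, partition))
    curve = robustness_curve(
        net, config.robustness_repetitions, config.robustness_seed
    )
    indices["robustness"] = robustness_scalar(curve, config.robustness_at)
    try:
        vuln = vulnerability(net)
        indices["vulnerability"] = vuln.V
    except Exception:
        vuln = None
        indices["vulnerability"] = float("nan")
    return net, indices, partition, roles, curve, vuln


def mantel_functions(function_table, community, n_permutations, seed):
    """Per-category Mantel tests of function profiles vs community
    Bray-Curtis distances for one group of samples."""
    community_distance = bray_curtis(community)
    rows = []
    for offset, category in enumerate(FUNCTION_CATEGORIES):
        profile = function_table.values.loc[category]
        result = mantel(
            euclidean_profile_distance(profile),
            community_distance,
            n_permutations=n_permutations,
            seed=seed + offset,
            category=category,
        )
        rows.append(dict(category=category, r=result.r, p=result.p))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run the full analysis and write all reports under ``outdir``."""
    start = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    soils = load_soils(config)

    index_rows = []
    networks: dict = {}
    partitions: dict = {}
    role_tables: dict = {}
    for soil_name, soil in soils.items():
        soil_dir = outdir / soil_name
        soil_dir.mkdir(exist_ok=True)
        for level in TREATMENT_LEVELS:
            if level not in soil.tables:
                continue
            label = f"{soil_name}_{level}"
            net, indices, partition, roles, curve, vuln = analyze_group(
                soil.tables[level], config,
                provenance=dict(soil=soil_name, treatment=level),
            )
            networks[(soil_name, level)] = net
            partitions[(soil_name, level)] = partition
            role_tables[(soil_name, level)] = roles

            cio.write_network(net, soil_dir / f"{label}_edges.tsv")
            attrs = roles.copy()
            attrs.insert(0, "phylum", [
                soil.taxonomy.get(t, "Others") for t in attrs.index
            ])
            attrs.to_csv(soil_dir / f"{label}_nodes.tsv", sep="\t")
            composition = node_phylum_composition(net, soil.taxonomy)
            composition.round(2).to_csv(
                soil_dir / f"{label}_phylum_composition.tsv", sep="\t",
                index_label="phylum",
            )
            pd.DataFrame(
                dict(fraction=curve.fractions, mean=curve.mean, sd=curve.sd)
            ).to_csv(soil_dir / f"{label}_robustness.tsv", sep="\t", index=False)
            if vuln is not None:
                cio.write_json(vuln.as_dict(), soil_dir / f"{label}_vulnerability.json")
            index_rows.append(dict(soil=soil_name, treatment=level, **indices))

    index_frame = pd.DataFrame(index_rows)
    index_frame.to_csv(outdir / "network_indices.tsv", sep="\t", index=False)

    comparison_rows = []
    mantel_frames = []
    for soil_name, soil in soils.items():
        soil_dir = outdir / soil_name
        control = networks.get((soil_name, "CK"))
        for level in TREATMENT_LEVELS:
            if level in soil.functions and level in soil.tables:
                frame = mantel_functions(
                    soil.functions[level], soil.tables[level],
                    config.n_permutations, config.permutation_seed,
                )
                frame.insert(0, "treatment", level)
                frame.insert(0, "soil", soil_name)
                mantel_frames.append(frame)
        if control is None:
            continue
        for level in DOSE_LEVELS:
            if (soil_name, level) not in networks:
                continue
            treated = networks[(soil_name, level)]
            combined = _concat_groups(soil.tables["CK"], soil.tables[level])
            groups = list(combined.metadata["treatment"])
            comparison = compare_networks(
                control, treated, combined, groups,
                part_a=partitions[(soil_name, "CK")],
                part_b=partitions[(soil_name, level)],
                variant=config.dissimilarity_variant,
                n_permutations=config.n_permutations,
                seed=config.permutation_seed,
                min_module_size=config.min_module_size,
                alpha=config.alpha,
            )
            overlap = keystone_overlap(
                role_tables[(soil_name, "CK")], role_tables[(soil_name, level)]
            )
            row = dict(soil=soil_name, pair=f"CK vs. {level}",
                       **comparison.as_dict(),
                       keystones_control=overlap["keystones_a"],
                       keystones_treatment=overlap["keystones_b"],
                       shared_keystones=overlap["shared"])
            comparison_rows.append(row)
            preserved_frame = pd.DataFrame([
                dict(pair=f"{soil_name}CK_M{p.module_a}:{soil_name}{level}_M{p.module_b}",
                     overlapping=p.a, only_module_1=p.b, only_module_2=p.c,
                     absent_from_both=p.d, p=p.p, p_adjusted=p.p_adjusted,
                     preserved=p.preserved)
                for p in comparison.preserved
            ])
            preserved_frame.to_csv(
                soil_dir / f"{soil_name}_CK_vs_{level}_preserved_modules.tsv",
                sep="\t", index=False,
            )

    pd.DataFrame(comparison_rows).to_csv(
        outdir / "network_comparisons.tsv", sep="\t", index=False
    )
    if mantel_frames:
        pd.concat(mantel_frames, ignore_index=True).to_csv(
            outdir / "function_mantel.tsv", sep="\t", index=False
        )

    deltas = summarize_deltas(index_frame)
    cio.write_json(deltas, outdir / "deltas.json")

    manifest = dict(
        config=config.to_dict(),
        versions=dict(
            python=platform.python_version(),
            numpy=np.__version__,
            pandas=pd.__version__,
            networkx=nx.__version__,
        ),
        wall_clock_seconds=round(time.time() - start, 3),
    )
    cio.write_json(manifest, outdir / "manifest.json")
    return outdir


def _concat_groups(table_a: AbundanceTable, table_b: AbundanceTable) -> AbundanceTable:
    values = pd.concat([table_a.values, table_b.values], axis=1)
    metadata = pd.concat([table_a.metadata, table_b.metadata])
    return AbundanceTable(values.fillna(0.0), metadata)


def summarize_deltas(indices: pd.DataFrame) -> dict:
    """Control-minus-treatment differences per soil.

    For each soil with a CK row: the decrease (CK minus treatment) in
    total nodes, total links and average degree for every dose level,
    with min/max ranges, plus — when present — the robustness decrease
    and the *signed* vulnerability change (treatment minus CK; a positive
    value means the treated network is more vulnerable).
    """
    out: dict = {}
    for soil_name, soil_frame in indices.groupby("soil"):
        frame = soil_frame.set_index("treatment")
        if "CK" not in frame.index:
            raise ValueError(f"soil {soil_name!r} has no control (CK) network")
        control = frame.loc["CK"]
        doses = [t for t in DOSE_LEVELS if t in frame.index]
        record: dict = {}
        for column, key in [
            ("total_nodes", "node_decrease"),
            ("total_links", "link_decrease"),
            ("average_degree", "degree_decrease"),
            ("robustness", "robustness_decrease"),
        ]:
            if column not in frame.columns:
                continue
            decreases = {
                t: float(control[column]) - float(frame.loc[t, column])
                for t in doses
            }
            record[key] = dict(
                per_treatment=decreases,
                min=min(decreases.values()),
                max=max(decreases.values()),
            )
        if "vulnerability" in frame.columns:
            changes = {
                t: float(frame.loc[t, "vulnerability"]) - float(control["vulnerability"])
                for t in doses
            }
            record["vulnerability_change"] = dict(
                per_treatment=changes,
                min=min(changes.values()),
                max=max(changes.values()),
            )
        out[str(soil_name)] = record
    return out


def load_indices(run_dir) -> pd.DataFrame:
    return pd.read_csv(Path(run_dir) / "network_indices.tsv", sep="\t")


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=True)


def save_run_metadata(config: RunConfig, outdir) -> None:
    write_config(config, Path(outdir) / "config.yaml")


def _read_json(path) -> dict:
    with open(path) as handle:
        return json.load(handle)
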
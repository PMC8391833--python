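"""Config-driven orchestration of the full analysis chain.

A run config (YAML or dict) names the input files, the marker type and the
analyses to perform; :func:`run` executes the stages in dependency order
(typing -> diversity/distances -> AMOVA/ordination/network; Y-STR runs add
ranking -> cores -> clusters -> TMRCA), writes every report as TSV into
the output directory, and records a manifest (parameters, seed, input
checksums, package version) sufficient to reproduce every number.
Identical config + inputs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clusters as dc
from . import diversity as dv
from . import io as uio
from . import mtdna as mt
from . import network as net
from . import ordination as ordn
from . import structure as st


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run(config: dict, out_dir: str | Path) -> Path:
    """Execute the configured analyses; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = config.get("marker")
    if marker not in ("mtdna", "ystr"):
        raise ConfigError(f"marker must be 'mtdna' or 'ystr', got {marker!r}")
    analyses = config.get(
        "analyses",
        ["diversity", "distances", "amova", "ordination", "network", "clusters"],
    )
    seed = int(config.get("seed", 0))
    grouping = config.get("grouping", "language_family")
    if grouping not in ("language_family", "country"):
        raise ConfigError(f"unknown grouping variable {grouping!r}")
    inputs = {}
    for key in ("fasta", "str_table", "metadata", "reference", "motifs"):
        if key in config:
            p = Path(config[key])
            if not p.exists():
                raise ConfigError(f"input file for {key!r} does not exist: {p}")
            inputs[key] = p

    if "metadata" not in inputs:
        raise ConfigError("a metadata TSV is required")
    meta = uio.read_metadata(inputs["metadata"])

    manifest: dict = {
        "package": "unipargen",
        "version": __version__,
        "marker": marker,
        "grouping": grouping,
        "seed": seed,
        "analyses": analyses,
        "parameters": {k: v for k, v in config.items() if k not in inputs},
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "outputs": [],
    }

    def emit(df: pd.DataFrame, name: str, **kw) -> None:
        _write(df, out / name, **kw)
        manifest["outputs"].append(name)

    if marker == "mtdna":
        if "fasta" not in inputs:
            raise ConfigError("mtdna marker requires a 'fasta' input")
        reference = mt.load_reference(inputs.get("reference"))
        panel = (
            mt.read_motif_panel(inputs["motifs"], reference)
            if "motifs" in inputs
            else mt.load_default_motifs(reference)
        )
        records = uio.read_fasta(inputs["fasta"])
        genomes = mt.type_genomes(records, reference, panel, meta)
        emit(mt.calls_table(genomes), "haplogroup_calls.tsv", index=False)
        freq = mt.haplogroup_frequency_table(genomes, meta)
        emit(freq, "haplogroup_frequencies.tsv")

        by_pop: dict[str, list[str]] = {}
        for g in genomes:
            m = g.meta or meta[g.sample_id]
            by_pop.setdefault(m.population, []).append(
                mt.apply_variants(reference, g.filtered_variants)
            )
        if "diversity" in analyses:
            reports = {
                p: dv.sequence_diversity(seqs)
                for p, seqs in by_pop.items()
                if len(seqs) >= 2
            }
            emit(dv.diversity_table(reports), "diversity.tsv", index=False)
        phi = None
        if "distances" in analyses and len(by_pop) >= 2:
            phi = st.pairwise_phi_st(by_pop)
            uio.write_distance_matrix(
                phi.to_numpy(), list(phi.index), out / "phi_st.tsv"
            )
            manifest["outputs"].append("phi_st.tsv")
        if "amova" in analyses and len(by_pop) >= 2:
            seqs, pops, grps = [], [], []
            for g in genomes:
                m = g.meta or meta[g.sample_id]
                seqs.append(mt.apply_variants(reference, g.filtered_variants))
                pops.append(m.population)
                grps.append(getattr(m, grouping))
            d2 = st.sequence_distance_matrix(seqs)
            two_level = 2 <= len(set(grps)) < len(set(pops))
            res = st.amova(
                d2,
                pops,
                grps if two_level else None,
                n_perm=int(config.get("n_perm", 999)),
                seed=seed,
            )
            emit(st.amova_table(res), "amova.tsv", index=False)
        if "ordination" in analyses:
            if freq.shape[0] >= 2:
                p = ordn.pca(freq)
                emit(p.coordinates, "pca_coordinates.tsv")
            if phi is not None and phi.shape[0] >= 3:
                m = ordn.nmds(phi, seed=seed)
                emit(m.coordinates, "nmds_coordinates.tsv")
                (out / "nmds_stress.txt").write_text(f"{m.stress:.6f}\n")
                manifest["outputs"].append("nmds_stress.txt")
        if "network" in analyses:
            chars, labels = net.mtdna_characters(genomes)
            if len(set(chars)) >= 2:
                weights = net.default_mtdna_weights(genomes, labels)
                hg = net.build_mj_network(chars, weights, epsilon=float(config.get("epsilon", 0.0)))
                pops = [(g.meta or meta[g.sample_id]).population for g in genomes]
                annotated = net.annotate_network(hg, chars, pops)
                uio.write_network_graphml(annotated, out / "mj_network.graphml")
                emit(net.node_table(annotated), "mj_network_nodes.tsv", index=False)
                manifest["outputs"].append("mj_network.graphml")

    else:  # ystr
        if "str_table" not in inputs:
            raise ConfigError("ystr marker requires a 'str_table' input")
        haplos, excluded = uio.read_str_table(inputs["str_table"], meta=meta)
        if excluded:
            pd.DataFrame({"sample_id": excluded}).to_csv(
                out / "excluded_samples.tsv", sep="\t", index=False
            )
            manifest["outputs"].append("excluded_samples.tsv")
        by_pop: dict[str, list] = {}
        for h in haplos:
            m = h.meta or meta.get(h.sample_id)
            if m is None:
                raise ValueError(f"no metadata for sample {h.sample_id!r}")
            by_pop.setdefault(m.population, []).append(h)
        if "diversity" in analyses:
            reports = {
                p: dv.str_diversity(hs) for p, hs in by_pop.items() if len(hs) >= 2
            }
            emit(dv.diversity_table(reports), "diversity.tsv", index=False)
        rst = None
        eligible = {p: hs for p, hs in by_pop.items() if len(hs) >= 2}
        if "distances" in analyses and len(eligible) >= 2:
            rst = st.pairwise_r_st(eligible)
            uio.write_distance_matrix(rst.to_numpy(), list(rst.index), out / "r_st.tsv")
            manifest["outputs"].append("r_st.tsv")
        if "amova" in analyses and len(eligible) >= 2:
            hs_all = [h for hs in eligible.values() for h in hs]
            mat = np.array([h.alleles for h in hs_all], dtype=float)
            pops = [(h.meta or meta[h.sample_id]).population for h in hs_all]
            grps = [getattr(h.meta or meta[h.sample_id], grouping) for h in hs_all]
            d2 = st.str_squared_distance_matrix(mat)
            two_level = 2 <= len(set(grps)) < len(set(pops))
            res = st.amova(
                d2,
                pops,
                grps if two_level else None,
                n_perm=int(config.get("n_perm", 999)),
                seed=seed,
            )
            emit(st.amova_table(res), "amova.tsv", index=False)
        if "ordination" in analyses and rst is not None and rst.shape[0] >= 3:
            m = ordn.nmds(rst, seed=seed)
            emit(m.coordinates, "nmds_coordinates.tsv")
            (out / "nmds_stress.txt").write_text(f"{m.stress:.6f}\n")
            manifest["outputs"].append("nmds_stress.txt")
        if "network" in analyses:
            chars = net.str_characters(haplos)
            if len(set(chars)) >= 2:
                hg = net.build_mj_network(
                    chars, mode="ordinal", epsilon=float(config.get("epsilon", 0.0))
                )
                pops = [(h.meta or meta[h.sample_id]).population for h in haplos]
                annotated = net.annotate_network(hg, chars, pops)
                uio.write_network_graphml(annotated, out / "mj_network.graphml")
                emit(net.node_table(annotated), "mj_network_nodes.tsv", index=False)
                manifest["outputs"].append("mj_network.graphml")
        if "clusters" in analyses:
            cfg = dc.TmrcaConfig(
                mu=float(config.get("mu", 0.022)),
                generation_years=float(config.get("generation_years", 30.0)),
                n_bootstrap=int(config.get("n_bootstrap", 1000)),
                seed=seed,
            )
            min_count = config.get("min_count")
            found, unassigned = dc.find_descent_clusters(
                haplos,
                meta,
                min_count=None if min_count is None else int(min_count),
                core_fraction=float(config.get("core_fraction", 0.01)),
                d_max=int(config.get("d_max", 2)),
                tmrca_config=cfg,
            )
            emit(
                dc.cluster_table(found, sampling_year=int(config.get("sampling_year", 2000))),
                "descent_clusters.tsv",
                index=False,
            )
            emit(dc.membership_table(found, unassigned, meta), "cluster_members.tsv", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
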
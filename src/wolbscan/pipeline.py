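"""End-to-end pipeline orchestration: simulate (optional) -> summarise ->
detect -> calibrate -> call haplotypes -> network -> ordination ->
prevalence summaries.

The pipeline is driven by a :class:`PipelineConfig`; a flat ``key=value``
text file can seed it and CLI flags override file values.  Every run
writes a manifest (JSON) listing each artifact with a SHA-256 checksum and
per-stage record counts; identical config and seed give identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from wolbscan import alignment, detect, haplotypes, network, ordination
from wolbscan import simulate as sim
from wolbscan.errors import ConfigError, PipelineError

__all__ = ["PipelineConfig", "validate_config", "parse_config_file",
           "run_pipeline"]

log = logging.getLogger("wolbscan")


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run."""

    outdir: str = "wolbscan_out"
    seed: int = 0
    # inputs; when reads_path is None the synthetic generator runs first
    reads_path: str | None = None
    depths_path: str | None = None
    gold_path: str | None = None
    dialect: str = "sam"
    id_delimiter: str = "|"
    # detection
    min_reads: int = 5
    min_len: int = 80
    mapq_min: int = 20
    exclude_mask: int = alignment.DEFAULT_EXCLUDE_MASK
    # haplotype filtering
    max_missing: float = 0.25
    # networks
    confidence: float = 0.95
    connection_limit: int | None = None
    min_major: int = 11
    # synthetic generator (scaled-down defaults for an end-to-end run)
    simulate: sim.SimulationConfig = field(
        default_factory=lambda: sim.SimulationConfig(
            n_localities=12, individuals_per_locality=(10, 25),
            infected_read_count_dist=("negative_binomial",
                                      {"mean": 300.0, "dispersion": 1.0}),
        ))

    def validate(self) -> "PipelineConfig":
        errs = []
        if self.min_reads < 1:
            errs.append("min_reads must be >= 1")
        if self.min_len < 1:
            errs.append("min_len must be >= 1")
        if self.mapq_min < 0:
            errs.append("mapq_min must be >= 0")
        if not 0 <= self.max_missing <= 1:
            errs.append("max_missing must be in [0, 1]")
        if not 0 < self.confidence < 1:
            errs.append("confidence must be in (0, 1)")
        if self.dialect not in ("sam", "tsv"):
            errs.append(f"unknown dialect '{self.dialect}'")
        if self.connection_limit is not None and self.connection_limit < 1:
            errs.append("connection_limit must be >= 1")
        for p in (self.reads_path, self.depths_path, self.gold_path):
            if p is not None and not Path(p).exists():
                errs.append(f"input path does not exist: {p}")
        if errs:
            raise ConfigError("; ".join(errs))
        try:
            self.simulate.validate()
        except ConfigError as exc:
            raise ConfigError(f"simulate: {exc}") from exc
        return self


_SIM_KEYS = {f.name for f in dataclasses.fields(sim.SimulationConfig)}
_PIPE_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)} - {
    "simulate"}
_INT_KEYS = {"seed", "min_reads", "min_len", "mapq_min", "exclude_mask",
             "connection_limit", "min_major", "n_localities", "n_strains",
             "n_sites", "individuals_per_locality"}
_FLOAT_KEYS = {"max_missing", "confidence", "strain_divergence",
               "within_strain_mutations", "prevalence_per_locality",
               "pcr_sensitivity", "pcr_specificity",
               "haplotype_concentration"}


def parse_config_file(path) -> dict:
    """Parse a flat ``key=value`` config file ('#' comments allowed)."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(
                    f"{path}:{lineno}: expected key=value, got '{line}'")
            key, value = (s.strip() for s in line.split("=", 1))
            out[key] = value
    return out


def validate_config(options: dict | PipelineConfig) -> PipelineConfig:
    """Normalise a key-value mapping into a validated PipelineConfig.

    Unknown keys are rejected; simulation keys (``sim.<name>`` or bare
    generator field names) are routed to the embedded generator config.
    All errors are aggregated into one message.
    """
    if isinstance(options, PipelineConfig):
        return options.validate()
    cfg = PipelineConfig()
    errs = []
    for raw_key, value in options.items():
        key = raw_key.removeprefix("sim.")
        if raw_key.startswith("sim."):
            target = cfg.simulate if key in _SIM_KEYS else None
        elif key in _PIPE_KEYS:
            target = cfg
        elif key in _SIM_KEYS:
            target = cfg.simulate
        else:
            target = None
        if target is None:
            errs.append(f"unknown configuration key '{raw_key}'")
            continue
        try:
            if isinstance(value, str):
                if key in _INT_KEYS:
                    value = int(value)
                elif key in _FLOAT_KEYS:
                    value = float(value)
                elif value.lower() in ("true", "false"):
                    value = value.lower() == "true"
            setattr(target, key, value)
        except ValueError as exc:
            errs.append(f"bad value for '{raw_key}': {exc}")
    if errs:
        raise ConfigError("; ".join(errs))
    return cfg.validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run every stage and return the output manifest.

    The manifest records the validated parameters, per-stage record
    counts, and every written artifact with its checksum.  A stage failure
    raises :class:`PipelineError` naming the stage.
    """
    config = validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"parameters": _config_dict(config), "stages": {},
                      "outputs": {}}

    def emit(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path),
                                     "sha256": _sha256(path)}

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s: start", name)
                counts = fn() or {}
                manifest["stages"][name] = counts
                log.info("stage %s: %s", name, counts)
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                manifest["stages"][name] = {"failed": str(exc)}
                (outdir / "manifest.json").write_text(
                    json.dumps(manifest, indent=2, default=str))
                raise PipelineError(name, exc) from exc
        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        if config.reads_path is not None:
            state["reads_src"] = (config.reads_path, config.dialect)
            state["depths"] = pd.read_csv(config.depths_path, sep="\t",
                                          comment="#") \
                if config.depths_path else None
            state["gold"] = _read_gold(config.gold_path) \
                if config.gold_path else None
            state["truth"] = None
            return {"skipped": "external inputs supplied"}
        sc = dataclasses.replace(config.simulate, seed=config.seed)
        truth = sim.simulate_truth(sc)
        reads, depths = sim.simulate_read_data(sc, truth)
        labels = sim.simulate_pcr_labels(
            truth, sc.pcr_sensitivity, sc.pcr_specificity,
            seed=config.seed + 1, subset_size=min(128, len(
                truth.individuals)))
        reads_path = outdir / ("reads.sam" if config.dialect == "sam"
                               else "reads.tsv")
        if config.dialect == "sam":
            sim.write_sam(reads, reads_path, sc,
                          id_delimiter=config.id_delimiter)
        else:
            sim.write_reads_tsv(reads, reads_path, sc)
        sim.write_depths_tsv(depths, outdir / "depths.tsv", sc)
        truth.individuals.to_csv(outdir / "truth.csv", index=False)
        labels.to_csv(outdir / "pcr_labels.csv", index=False)
        for nm in ("reads.sam" if config.dialect == "sam" else "reads.tsv",
                   "depths.tsv", "truth.csv", "pcr_labels.csv"):
            emit(nm, outdir / nm)
        state.update(
            reads_src=(reads_path, config.dialect), depths=depths,
            gold=dict(zip(labels.individual_id, labels.pcr_positive)),
            truth=truth)
        return {"individuals": len(truth.individuals), "reads": len(reads)}

    @stage("summarize")
    def _summarize():
        path, dialect = state["reads_src"]
        records = alignment.read_alignments(path, dialect,
                                            config.id_delimiter)
        summaries = alignment.summarize_reads(
            records, mapq_min=config.mapq_min,
            exclude_mask=config.exclude_mask)
        if state.get("truth") is not None:
            # hosts with no mapped reads produce no alignment records but
            # are still part of the cohort (and called uninfected)
            for iid in state["truth"].individuals.individual_id:
                summaries.setdefault(
                    iid, alignment.IndividualReadSummary(iid))
        alignment.write_summary_csv(summaries, outdir / "read_summary.csv",
                                    len_min=config.min_len)
        emit("read_summary.csv", outdir / "read_summary.csv")
        state["summaries"] = summaries
        return {"individuals": len(summaries)}

    @stage("detect")
    def _detect():
        calls = detect.classify_infection(
            state["summaries"], config.min_reads, config.min_len)
        calls.to_frame().to_csv(outdir / "infection_calls.csv",
                                index=False)
        emit("infection_calls.csv", outdir / "infection_calls.csv")
        state["calls"] = calls
        return {"called": len(calls.calls), "infected": calls.n_infected}

    @stage("calibrate")
    def _calibrate():
        if not state.get("gold"):
            return {"skipped": "no gold labels"}
        frame, _ = detect.threshold_sweep(
            state["summaries"], state["gold"],
            read_grid=detect.DEFAULT_READ_GRID,
            len_grid=(config.min_len,))
        frame.to_csv(outdir / "threshold_sweep.csv", index=False)
        emit("threshold_sweep.csv", outdir / "threshold_sweep.csv")
        best = frame[frame.best].iloc[0]
        return {"grid_rows": len(frame),
                "best_min_reads": int(best.min_reads)}

    @stage("haplotypes")
    def _haplotypes():
        if state.get("depths") is None:
            return {"skipped": "no depth table"}
        mat = haplotypes.call_haploid(state["depths"])
        infected = [i for i, c in state["calls"].calls.items() if c]
        mat = haplotypes.filter_sites(mat, config.max_missing,
                                      individuals=infected)
        mat = haplotypes.filter_complete_individuals(mat)
        state["matrix"] = mat
        if mat.n_individuals == 0 or mat.n_sites == 0:
            return {"individuals": 0, "sites": mat.n_sites}
        haplotypes.write_vcf(mat, outdir / "haplotypes.vcf")
        haplotypes.export_nexus(mat, outdir / "haplotypes.nex")
        haplotypes.write_haplotype_fasta(mat, outdir / "haplotypes.fasta")
        for nm in ("haplotypes.vcf", "haplotypes.nex", "haplotypes.fasta"):
            emit(nm, outdir / nm)
        return {"individuals": mat.n_individuals, "sites": mat.n_sites}

    @stage("network")
    def _network():
        mat = state.get("matrix")
        if mat is None or mat.n_individuals == 0:
            return {"skipped": "no haplotypes"}
        haps, mult, ind_to_hap = mat.unique_haplotypes()
        dist = network.hamming_matrix(haps)
        net = network.build_network(dist, mult,
                                    limit=config.connection_limit,
                                    confidence=config.confidence)
        assignment = network.assign_strains(net, ind_to_hap,
                                            config.min_major)
        net.to_edge_frame().to_csv(outdir / "network_edges.csv",
                                   index=False)
        assignment.to_frame().to_csv(outdir / "strain_assignment.csv",
                                     index=False)
        network.haplotype_spectrum(assignment).to_csv(
            outdir / "strain_spectrum.csv", index=False)
        for nm in ("network_edges.csv", "strain_assignment.csv",
                   "strain_spectrum.csv"):
            emit(nm, outdir / nm)
        state.update(haps=haps, dist=dist, net=net,
                     assignment=assignment, ind_to_hap=ind_to_hap)
        return {"haplotypes": len(haps), "components": len(net.components),
                "connection_limit": net.connection_limit}

    @stage("ordination")
    def _ordination():
        if "dist" not in state:
            return {"skipped": "no network"}
        res = ordination.pcoa(state["dist"])
        res.to_frame().to_csv(outdir / "pcoa_coordinates.csv")
        pd.DataFrame({"eigenvalue": res.eigenvalues,
                      "proportion": res.proportion_explained}).to_csv(
            outdir / "pcoa_eigenvalues.csv", index=False)
        div = ordination.divergence_table(state["haps"],
                                          state["assignment"])
        div.mean.to_csv(outdir / "divergence_mean.csv")
        div.sd.to_csv(outdir / "divergence_sd.csv")
        for nm in ("pcoa_coordinates.csv", "pcoa_eigenvalues.csv",
                   "divergence_mean.csv", "divergence_sd.csv"):
            emit(nm, outdir / nm)
        return {"axes": int((res.eigenvalues > 0).sum())}

    @stage("summaries")
    def _summaries():
        truth = state.get("truth")
        if truth is None:
            return {"skipped": "no locality metadata"}
        meta = truth.individuals[["individual_id", "locality", "lineage"]]
        by_loc = detect.prevalence_by_group(state["calls"], meta,
                                            "locality")
        by_lin = detect.prevalence_by_group(state["calls"], meta,
                                            "lineage")
        by_loc.to_csv(outdir / "prevalence_by_locality.csv", index=False)
        by_lin.to_csv(outdir / "prevalence_by_lineage.csv", index=False)
        for nm in ("prevalence_by_locality.csv",
                   "prevalence_by_lineage.csv"):
            emit(nm, outdir / nm)
        return {"localities": len(by_loc), "lineages": len(by_lin)}

    try:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n")
    finally:
        log.removeHandler(handler)
        handler.close()
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _read_gold(path) -> dict[str, bool]:
    df = pd.read_csv(path)
    col = "pcr_positive" if "pcr_positive" in df.columns else df.columns[1]
    return dict(zip(df.individual_id, df[col].astype(bool)))
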
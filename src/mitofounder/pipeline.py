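"""End-to-end orchestration: profiles -> classification -> tree -> dating ->
consensus -> routes, with a serialized config and a per-stage log so any run
is reproducible from its output directory."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import clock as clk
from . import founder as fd
from . import haplotree as ht
from . import mito_io as mio
from . import synthetic_data as syn


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


@dataclass
class RunConfig:
    sequences: str | None = None          # FASTA of sample mitogenomes
    sample_sheet: str | None = None       # TSV: sample_id, region_label[, haplogroup]
    reference: str = "synthetic"          # FASTA path or "synthetic"
    mask: str = "default"                 # default | none | path to mask TSV
    reference_tree: str | None = None     # motif tree TSV for classification
    route_table: str | None = None
    route_overrides: str | None = None
    methods: tuple[str, ...] = ("rho", "ml")
    model_kind: str = "TN93"
    gamma_shape: float | None = None
    n_categories: int = 32
    z: float = 1.96
    years_per_substitution: float = clk.YEARS_PER_SUBSTITUTION
    correction: str | None = None
    seed: int = 1
    out_dir: str = "run_out"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return RunConfig(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["methods"] = list(d["methods"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _load_mask(spec: str) -> mio.SiteMask | None:
    if spec == "default":
        return mio.default_mask()
    if spec == "none":
        return None
    df = pd.read_csv(spec, sep="\t", dtype=str).fillna("")
    pos, ind, alle = set(), set(), set()
    for r in df.itertuples():
        p = int(r.position)
        if r.kind == "indel":
            ind.add(p)
        elif r.kind == "allele":
            alle.add((p, r.allele))
        else:
            pos.add(p)
    return mio.SiteMask(frozenset(pos), frozenset(ind), frozenset(alle))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the run report (also written to
    ``out_dir/report.json``).  Any stage failure aborts with the stage name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: list[str] = [f"seed={config.seed}"]
    report: dict = {"seed": config.seed}

    def fail(stage: str, exc: Exception):
        raise PipelineError(stage, str(exc)) from exc

    # --- inputs -----------------------------------------------------------
    try:
        if config.reference == "synthetic":
            ref = syn.synthetic_reference()
        else:
            ref = mio.load_reference(config.reference)
        if not config.sequences:
            raise mio.FormatError("no input sequences configured")
        seqs = mio.load_fasta(config.sequences)
        if not seqs:
            raise mio.FormatError(f"input FASTA {config.sequences} contains no records")
        region_of_sample: dict[str, str] = {}
        hap_of_sample: dict[str, str] = {}
        if config.sample_sheet:
            sheet = mio.read_sample_sheet(config.sample_sheet)
            if "region_label" in sheet.columns:
                region_of_sample = dict(zip(sheet["sample_id"], sheet["region_label"]))
            if "haplogroup" in sheet.columns:
                hap_of_sample = dict(zip(sheet["sample_id"], sheet["haplogroup"]))
        log.append(f"inputs: {len(seqs)} sequences")
        report["n_sequences"] = len(seqs)
    except PipelineError:
        raise
    except Exception as e:
        fail("inputs", e)

    # --- variant calling --------------------------------------------------
    try:
        profiles = [
            mio.call_variants(s, ref, sample_id=sid,
                              region_label=region_of_sample.get(sid, ""))
            for sid, s in sorted(seqs.items())
        ]
        mio.write_profiles_tsv(out / "profiles_raw.tsv", profiles)
    except Exception as e:
        fail("call_variants", e)

    # --- masking ----------------------------------------------------------
    try:
        mask = _load_mask(config.mask)
        if mask is not None:
            profiles = [mio.apply_mask(p, mask) for p in profiles]
        n_masked = sum(p.masked_removed for p in profiles)
        mio.write_profiles_tsv(out / "profiles.tsv", profiles)
        log.append(f"masking: {n_masked} variants removed")
        report["n_masked_variants"] = n_masked
    except Exception as e:
        fail("mask", e)

    # --- classification ---------------------------------------------------
    calls = None
    try:
        if config.reference_tree:
            ref_tree = ht.read_reference_tree(config.reference_tree)
            calls = [ht.classify(p, ref_tree) for p in profiles]
            pd.DataFrame([{
                "sample_id": c.sample_id, "haplogroup": c.best_label,
                "score": c.score, "path_depth": c.path_depth,
            } for c in calls]).to_csv(out / "haplogroup_calls.tsv", sep="\t", index=False)
            # sample-sheet haplogroups (curated) take precedence over calls
            hap_of_sample = {**{c.sample_id: c.best_label for c in calls},
                             **hap_of_sample}
            log.append(f"classification: {len(calls)} calls")
    except Exception as e:
        fail("classify", e)

    # --- parsimony tree ---------------------------------------------------
    try:
        tree = ht.build_mp_tree(profiles)
        (out / "tree.nwk").write_text(ht.to_newick(tree) + "\n")
        ht.edge_table(tree).to_csv(out / "edges.tsv", sep="\t", index=False)
        n_haps = len(tree.tips())
        log.append(f"tree: {n_haps} haplotypes (from {len(profiles)} samples), "
                   f"parsimony score {tree.score}")
        report["parsimony_score"] = tree.score
        report["n_haplotypes"] = n_haps
    except Exception as e:
        fail("tree", e)

    # --- dating -----------------------------------------------------------
    estimates: list[clk.AgeEstimate] = []
    try:
        if config.correction:
            clock = clk.load_correction_table(config.correction)
        else:
            clock = clk.ClockModel(config.years_per_substitution)
        rows = []
        if "rho" in config.methods:
            r = clk.rho_sigma(tree, clade_id="all")
            est = clk.rho_age(r, clock, z=config.z)
            estimates.append(est)
            rows.append({"clade_id": "all", "method": "rho", "n": r.n,
                         "rho": r.rho, "sigma": r.sigma,
                         "age_years": est.age_years, "ci_low": est.ci_low_years,
                         "ci_high": est.ci_high_years})
        if "ml" in config.methods:
            model = clk.SubstitutionModel(
                config.model_kind,
                base_frequencies=clk._empirical_frequencies(seqs),
                gamma_shape=config.gamma_shape, n_categories=config.n_categories,
            ) if config.model_kind not in ("JC69", "K80") else clk.SubstitutionModel(
                config.model_kind, gamma_shape=config.gamma_shape,
                n_categories=config.n_categories)
            parts = (clk.PartitionScheme.default()
                     if len(next(iter(seqs.values()))) == mio.RCRS_LENGTH
                     else clk.PartitionScheme.single(len(next(iter(seqs.values())))))
            mask_obj = _load_mask(config.mask)
            excl = set(mask_obj.excluded_positions) if mask_obj else set()
            fit = clk.fit_clock_heights({**seqs}, tree, model, parts,
                                        exclude_positions=excl, seed=config.seed)
            est = clk.ml_age(fit, clock=clock, genome_length=len(ref))
            estimates.append(est)
            rows.append({"clade_id": est.clade_id, "method": "ml", "n": len(seqs),
                         "rho": float("nan"), "sigma": float("nan"),
                         "age_years": est.age_years, "ci_low": est.ci_low_years,
                         "ci_high": est.ci_high_years})
        pd.DataFrame(rows).to_csv(out / "ages.tsv", sep="\t", index=False)
        report["ages"] = rows
        log.append(f"dating: {len(rows)} estimates ({', '.join(config.methods)})")
    except Exception as e:
        fail("date", e)

    # --- consensus --------------------------------------------------------
    try:
        if estimates:
            ci = clk.consensus_interval(estimates)
            pd.DataFrame([{
                "low_years": ci.low, "high_years": ci.high, "empty": ci.empty,
            }]).to_csv(out / "consensus.tsv", sep="\t", index=False)
            report["consensus"] = {"low": ci.low, "high": ci.high, "empty": ci.empty}
            log.append(f"consensus: [{ci.low:.1f}, {ci.high:.1f}]"
                       + (" EMPTY" if ci.empty else ""))
    except Exception as e:
        fail("consensus", e)

    # --- routes -----------------------------------------------------------
    try:
        if config.route_table and hap_of_sample:
            routes = fd.read_route_table(config.route_table)
            overrides = (fd.read_overrides(config.route_overrides)
                         if config.route_overrides else None)
            ref_tree = (ht.read_reference_tree(config.reference_tree)
                        if config.reference_tree else None)
            rows = [(sid, region_of_sample.get(sid, ""), hg)
                    for sid, hg in sorted(hap_of_sample.items())]
            summaries = fd.attribute_routes(rows, routes, ref_tree, overrides)
            fd.summaries_to_frame(summaries).to_csv(
                out / "route_summary.tsv", sep="\t", index=False)
            report["routes"] = [dataclasses.asdict(s) for s in summaries]
            log.append(f"routes: {len(summaries)} region summaries")
    except Exception as e:
        fail("routes", e)

    (out / "log.txt").write_text("\n".join(log) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                default=str) + "\n")
    return report
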
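"""End-to-end experiment orchestration with manifest-based reproducibility.

One :class:`RunConfig` (YAML/JSON-serialisable, master seed mandatory)
drives the stages: build the synthetic universe, curate compound sets,
pretrain the SMILES model on the full universe, fine-tune it on the
multi-target training set, sample from checkpoints with one shared seed,
and run the four evaluation analyses plus the promiscuity classifier.

Every stage records its outputs and their SHA-256 hashes in a manifest;
re-invoking a finished run with an unchanged configuration is a no-op, and
all stage seeds are named children of the master seed so any stage can be
reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from ._seeds import derive_seed
from .curation import ClassThresholds, curate
from .evaluation import (
    classify_generated,
    neighbors,
    nll_summary,
    reduce_batch,
    retrieval,
    scaffold_analysis,
    train_classifier,
)
from .model import SmilesRnnGenerator
from .universe import (
    UniverseConfig,
    build_universe,
    write_assay_csv,
    write_smiles_file,
)

__all__ = ["RunConfig", "run_pipeline", "report", "evaluation_verdicts"]

VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Complete configuration of one experiment.

    ``seed`` is the master seed; every stage derives a named child seed from
    it. Sub-dicts override stage defaults (see the dataclass fields).
    """

    seed: int
    out_dir: str
    universe: dict = field(default_factory=lambda: {"n_multi": 50, "n_single": 1000, "n_none": 2000})
    curation: dict = field(default_factory=lambda: {"max_hit_rate": 0.02, "n_train": 30})
    generator: dict = field(default_factory=lambda: {"hidden_size": 128, "n_epochs": 60})
    finetune: dict = field(default_factory=lambda: {"n_epochs": 200, "randomize": True})
    sampling: dict = field(default_factory=lambda: {"n_per_epoch": 20000})
    evaluation: dict = field(
        default_factory=lambda: {
            "threshold": 0.6,
            "n_negative_per_class": 300,
            "classifier": True,
        }
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is required")
        self.seed = int(self.seed)
        if self.seed < 0:
            raise ValueError("master seed must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "seed" not in d:
            raise ValueError("run configuration must set a master seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        merged = {}
        for f in dataclasses.fields(cls):
            if f.name in ("seed", "out_dir"):
                continue
            default = f.default_factory()  # type: ignore[misc]
            default.update(d.get(f.name, {}))
            merged[f.name] = default
        return cls(seed=d["seed"], out_dir=d.get("out_dir", "promgen_run"), **merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(name: str, config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps({"stage": name, "config": config.to_dict()}, sort_keys=True).encode()
    ).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict[str, Any] = {"version": VERSION, "stages": {}, "child_seeds": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_done(self, name: str, key: str) -> bool:
        st = self.data["stages"].get(name)
        if not st or st.get("key") != key or st.get("status") != "complete":
            return False
        return all(
            Path(p).exists() and _sha256(Path(p)) == h for p, h in st["outputs"].items()
        )

    def record(self, name: str, key: str, outputs: list[Path], seconds: float) -> None:
        self.data["stages"][name] = {
            "key": key,
            "status": "complete",
            "seconds": round(seconds, 2),
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the manifest dict.

    Stages already marked complete in the output directory's manifest (with
    an identical configuration and intact output hashes) are skipped.
    On a stage failure the partial manifest is preserved on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    manifest = _Manifest(out / "run_manifest.json")
    seeds = {
        name: derive_seed(config.seed, name)
        for name in ("universe", "split", "finetune", "sampling", "classifier")
    }
    manifest.data["child_seeds"] = seeds
    manifest.data["config"] = config.to_dict()

    # ---- stage: universe -------------------------------------------------
    key = _stage_key("universe", config)
    compounds_path, records_path = out / "compounds.smi", out / "records.csv"
    if not manifest.stage_done("universe", key):
        t0 = time.time()
        ucfg = UniverseConfig(seed=seeds["universe"], **config.universe)
        uni = build_universe(ucfg)
        write_smiles_file(compounds_path, uni.compounds)
        write_assay_csv(records_path, uni.records)
        manifest.record("universe", key, [compounds_path, records_path], time.time() - t0)
    from .universe import read_assay_csv, read_smiles_file

    compounds = read_smiles_file(compounds_path)
    records = read_assay_csv(records_path)
    smiles_by_id = {cid: smi for smi, cid in compounds}

    # ---- stage: curate ---------------------------------------------------
    key = _stage_key("curate", config)
    set_paths = {n: out / f"{n}.smi" for n in ("multi_train", "multi_test", "single_test", "none_test")}
    audit_path = out / "curation_audit.json"
    cur_opts = dict(config.curation)
    thresholds = ClassThresholds(**cur_opts.pop("thresholds", {}))
    sets = curate(
        records, smiles_by_id, thresholds=thresholds, seed=seeds["split"], **cur_opts
    )
    if not manifest.stage_done("curate", key):
        t0 = time.time()
        for name, path in set_paths.items():
            write_smiles_file(path, [(s, c) for c, s in sets.set_items()[name].items()])
        audit_path.write_text(json.dumps(sets.audit, indent=2, default=str))
        manifest.record("curate", key, [*set_paths.values(), audit_path], time.time() - t0)

    # ---- stage: pretrain -------------------------------------------------
    key = _stage_key("pretrain", config)
    pretrained_path = out / "pretrained.npz"
    if not manifest.stage_done("pretrain", key):
        t0 = time.time()
        gen = SmilesRnnGenerator(random_state=config.seed, **config.generator)
        gen.fit([smi for smi, _ in compounds])
        gen.save(pretrained_path)
        pd.DataFrame(gen.trace_).to_csv(out / "pretrain_trace.csv", index=False)
        manifest.record(
            "pretrain", key, [pretrained_path, out / "pretrain_trace.csv"], time.time() - t0
        )

    # ---- stage: finetune + sample ---------------------------------------
    key = _stage_key("finetune", config)
    n_ft = int(config.finetune.get("n_epochs", 200))
    checkpoint_epochs = sorted(set(config.finetune.get("checkpoint_epochs", [0, n_ft])))
    sample_dir = out / "samples"
    sample_paths = [sample_dir / f"epoch_{e:04d}.smi" for e in checkpoint_epochs]
    trace_path = out / "finetune_trace.csv"
    if not manifest.stage_done("finetune", key):
        t0 = time.time()
        gen = SmilesRnnGenerator.load(pretrained_path)
        cks = gen.fine_tune(
            list(sets.multi_train.values()),
            n_epochs=n_ft,
            randomize=bool(config.finetune.get("randomize", True)),
            seed=seeds["finetune"],
            checkpoint_epochs=checkpoint_epochs,
        )
        sample_dir.mkdir(exist_ok=True)
        n_sample = int(config.sampling.get("n_per_epoch", 20000))
        for e, path in zip(checkpoint_epochs, sample_paths):
            raw = cks[e].sample(n_sample, seed=seeds["sampling"])
            with open(path, "w") as fh:
                fh.writelines(s + "\n" for s in raw)
            cks[e].save(out / f"checkpoint_{e:04d}.npz")
        pd.DataFrame(gen.trace_).to_csv(trace_path, index=False)
        manifest.record(
            "finetune", key,
            [trace_path, *sample_paths, *(out / f"checkpoint_{e:04d}.npz" for e in checkpoint_epochs)],
            time.time() - t0,
        )

    # ---- stage: evaluate -------------------------------------------------
    key = _stage_key("evaluate", config)
    eval_paths = {
        n: out / f"{n}.csv"
        for n in ("nll_summary", "retrieval", "neighbors", "scaffolds", "classified_fraction")
    }
    report_path = out / "evaluation_report.json"
    if not manifest.stage_done("evaluate", key):
        t0 = time.time()
        checkpoints = {
            e: SmilesRnnGenerator.load(out / f"checkpoint_{e:04d}.npz")
            for e in checkpoint_epochs
        }
        known = {n: list(m.values()) for n, m in sets.set_items().items()}
        batches = {}
        for e, path in zip(checkpoint_epochs, sample_paths):
            raw = [line.rstrip("\n") for line in open(path)]
            batches[e] = reduce_batch(raw, known, epoch=e)
        nll_df = nll_summary(checkpoints, sets)
        ret_df = pd.concat([retrieval(b, sets) for b in batches.values()], ignore_index=True)
        thr = float(config.evaluation.get("threshold", 0.6))
        nb_df = pd.concat(
            [neighbors(b, sets, threshold=thr) for b in batches.values()], ignore_index=True
        )
        sc_df = scaffold_analysis(batches, sets)
        outputs = [report_path]
        classifier_metrics: dict | None = None
        if config.evaluation.get("classifier", True):
            bundle = train_classifier(
                sets,
                n_negative_per_class=int(config.evaluation.get("n_negative_per_class", 300)),
                seed=seeds["classifier"],
            )
            cf_df = classify_generated(bundle, batches)
            classifier_metrics = bundle.metrics
            cf_df.to_csv(eval_paths["classified_fraction"], index=False)
            outputs.append(eval_paths["classified_fraction"])
        for df, name in ((nll_df, "nll_summary"), (ret_df, "retrieval"),
                         (nb_df, "neighbors"), (sc_df, "scaffolds")):
            df.to_csv(eval_paths[name], index=False)
            outputs.append(eval_paths[name])
        summary = {
            "epochs": checkpoint_epochs,
            "batch_stats": {
                e: {"n_raw": b.n_raw, "n_valid": b.n_valid, "n_unique": len(b.unique),
                    "n_novel": len(b.novel)}
                for e, b in batches.items()
            },
            "classifier": classifier_metrics,
        }
        report_path.write_text(json.dumps(summary, indent=2))
        manifest.record("evaluate", key, outputs, time.time() - t0)

    return manifest.data


def evaluation_verdicts(out_dir) -> dict[str, bool | None]:
    """Recompute the qualitative fine-tuning verdicts from the run's CSVs.

    Each verdict compares the first and last evaluated epochs:

    * ``nll_ordering``    -- multi-test median NLL below single- and
      no-target medians at the final epoch but not initially;
    * ``retrieval_ordering`` -- multi_train > multi_test > max(single, none)
      retrieval percentage at the final epoch;
    * ``neighbor_gain``   -- more neighbor pairs per known multi-test
      compound at the final epoch than initially;
    * ``novel_scaffolds`` -- at least one multi-test scaffold absent from
      the training set retrieved at the final epoch;
    * ``classifier_shift`` -- higher predicted multi-target fraction at the
      final epoch (None when the classifier stage did not run).
    """
    out = Path(out_dir)

    def med(df, epoch, name):
        return float(df[(df.epoch == epoch) & (df.set == name)]["median"].iloc[0])

    nll = pd.read_csv(out / "nll_summary.csv")
    ret = pd.read_csv(out / "retrieval.csv")
    nb = pd.read_csv(out / "neighbors.csv")
    sc = pd.read_csv(out / "scaffolds.csv")
    e0, e1 = int(nll.epoch.min()), int(nll.epoch.max())

    verdicts: dict[str, bool | None] = {}
    final_low = med(nll, e1, "multi_test") < med(nll, e1, "single_test") and med(
        nll, e1, "multi_test"
    ) < med(nll, e1, "none_test")
    initial_low = med(nll, e0, "multi_test") < med(nll, e0, "single_test") and med(
        nll, e0, "multi_test"
    ) < med(nll, e0, "none_test")
    verdicts["nll_ordering"] = bool(final_low and not initial_low)

    def pct(epoch, name):
        return float(ret[(ret.epoch == epoch) & (ret.set == name)]["pct"].iloc[0])

    verdicts["retrieval_ordering"] = bool(
        pct(e1, "multi_train") > pct(e1, "multi_test")
        and pct(e1, "multi_test") > max(pct(e1, "single_test"), pct(e1, "none_test"))
    )

    def ppk(epoch):
        sel = nb[(nb.epoch == epoch) & (nb.set == "multi_test")]
        return float(sel["pairs_per_known"].iloc[0])

    verdicts["neighbor_gain"] = bool(ppk(e1) > ppk(e0))

    final_sc = sc[(sc.epoch == e1) & (sc.set == "multi_test")]
    verdicts["novel_scaffolds"] = bool(final_sc["novel_test_retrieved"].iloc[0] >= 1)

    cf_path = out / "classified_fraction.csv"
    if cf_path.exists():
        cf = pd.read_csv(cf_path)
        first = float(cf[cf.epoch == e0]["fraction_multi"].iloc[0])
        last = float(cf[cf.epoch == e1]["fraction_multi"].iloc[0])
        verdicts["classifier_shift"] = bool(last > first)
    else:
        verdicts["classifier_shift"] = None
    return verdicts


def report(out_dir) -> str:
    """Human-readable summary of a completed run (tables + verdicts)."""
    out = Path(out_dir)
    missing = [
        n for n in ("nll_summary.csv", "retrieval.csv", "neighbors.csv", "scaffolds.csv")
        if not (out / n).exists()
    ]
    if missing:
        raise FileNotFoundError(f"evaluation outputs missing from {out}: {missing}")
    lines = [f"promgen run report -- {out}", "=" * 60]
    for name, title in (
        ("nll_summary", "NLL quartiles (nats) per epoch and set"),
        ("retrieval", "Exact retrieval per epoch and set"),
        ("neighbors", "Fingerprint neighbors (Tc >= threshold) per epoch and set"),
        ("scaffolds", "Bemis-Murcko scaffold retrieval per epoch and set"),
    ):
        df = pd.read_csv(out / f"{name}.csv")
        lines += ["", title, "-" * len(title), df.to_string(index=False)]
    cf_path = out / "classified_fraction.csv"
    lines += ["", "Classifier-predicted multi-target fraction", "-" * 42]
    if cf_path.exists():
        lines.append(pd.read_csv(cf_path).to_string(index=False))
        rep = json.loads((out / "evaluation_report.json").read_text())
        if rep.get("classifier"):
            lines.append(f"classifier metrics: {rep['classifier']}")
    else:
        lines.append("not run")
    lines += ["", "Fine-tuning verdicts", "-" * 20]
    for name, value in evaluation_verdicts(out).items():
        shown = "not run" if value is None else ("PASS" if value else "FAIL")
        lines.append(f"{name:>20}: {shown}")
    return "\n".join(lines) + "\n"
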
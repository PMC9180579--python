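"""File formats and model persistence.

Canonical tabular dialect is TSV (tab-delimited, header row, UTF-8).
Targets are read from FASTA (ids up to the first whitespace) or TSV;
outcome tables are (target_id, label, count) rows where ``label`` is
either a taxonomy codec string ("-5+4", "1+T", ...) or a raw sequencing
descriptor ("D4_L-6R-1", "I1_L-1R0_T").  Frequencies are written with 9+
significant digits so write/read round-trips are lossless at the
tolerances the pipeline checks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .embedding import GloveEmbedder, PositionedVocab
from .labels import LabelError, LabelSpace, aggregate_outcomes
from .network import ApindelNetwork, IndelOutcomePredictor
from .preprocess import TargetRecord
from .simulate import SimConfig

__all__ = [
    "read_targets",
    "write_targets_fasta",
    "read_outcomes",
    "attach_outcomes",
    "write_outcomes",
    "write_predictions",
    "read_predictions",
    "write_attention_profile",
    "save_embedding_tsv",
    "save_embedder",
    "load_embedder",
    "save_model",
    "load_model",
    "RunConfig",
    "load_run_config",
    "config_hash",
]

CHECKPOINT_SCHEMA = 1


# ---------------------------------------------------------------------------
# Targets


def read_targets(path: str | Path) -> list[TargetRecord]:
    """Read targets from FASTA (.fa/.fasta) or TSV with id/sequence columns."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        records = [
            TargetRecord(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    else:
        df = pd.read_csv(path, sep="\t")
        cols = {c.lower(): c for c in df.columns}
        id_col = cols.get("target_id") or cols.get("id")
        seq_col = cols.get("sequence") or cols.get("seq")
        if id_col is None or seq_col is None:
            raise LabelError(
                f"{path}: need target_id/id and sequence columns, got {list(df.columns)}"
            )
        records = [
            TargetRecord(id=str(r[id_col]), sequence=str(r[seq_col]).upper())
            for _, r in df.iterrows()
        ]
    if not records:
        raise LabelError(f"{path}: no target records found")
    return records


def write_targets_fasta(records: list[TargetRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Outcome tables


def read_outcomes(
    path: str | Path, space: LabelSpace
) -> tuple[dict[str, np.ndarray], list]:
    """Read a (target_id, label, count) TSV into per-target distributions.

    Returns (id -> normalized 557-vector, drop log of out-of-taxonomy rows).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"target_id", "label", "count"}
    if not required <= set(df.columns):
        raise LabelError(f"{path}: outcome TSV needs columns {sorted(required)}")
    out: dict[str, np.ndarray] = {}
    dropped: list = []
    for tid, grp in df.groupby("target_id", sort=False):
        rows = list(zip(grp["label"].astype(str), grp["count"].astype(float)))
        try:
            result = aggregate_outcomes(rows, space)
        except LabelError as err:
            raise LabelError(f"{path}: target {tid}: {err}") from err
        out[str(tid)] = result.distribution
        dropped.extend((str(tid), *d) for d in result.dropped)
    return out, dropped


def attach_outcomes(
    records: list[TargetRecord], outcomes: dict[str, np.ndarray]
) -> list[TargetRecord]:
    """Join outcome distributions onto target records by id."""
    missing = [r.id for r in records if r.id not in outcomes]
    if missing:
        raise LabelError(f"no outcomes for targets: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    for rec in records:
        rec.distribution = outcomes[rec.id]
    return records


def write_outcomes(
    records: list[TargetRecord], space: LabelSpace, path: str | Path,
    ground_truth: bool = False, min_frequency: float = 0.0,
) -> None:
    """Write per-target distributions as (target_id, label, count) rows."""
    strings = space.strings()
    with open(path, "w") as fh:
        fh.write("target_id\tlabel\tcount\n")
        for rec in records:
            p = rec.ground_truth if ground_truth else rec.distribution
            if p is None:
                raise LabelError(f"record {rec.id} has no distribution to write")
            for s, freq in zip(strings, np.asarray(p, float)):
                if freq > min_frequency:
                    fh.write(f"{rec.id}\t{s}\t{freq:.9e}\n")


def write_predictions(
    ids: list[str], predictions: np.ndarray, space: LabelSpace, path: str | Path
) -> None:
    """Prediction TSV: target_id, label, frequency (9 significant digits)."""
    P = np.asarray(predictions, dtype=float)
    strings = space.strings()
    with open(path, "w") as fh:
        fh.write("target_id\tlabel\tfrequency\n")
        for tid, p in zip(ids, P):
            for s, freq in zip(strings, p):
                fh.write(f"{tid}\t{s}\t{freq:.9e}\n")


def read_predictions(
    path: str | Path, space: LabelSpace
) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    index = {s: i for i, s in enumerate(space.strings())}
    ids = list(dict.fromkeys(df["target_id"].astype(str)))
    pos = {tid: n for n, tid in enumerate(ids)}
    P = np.zeros((len(ids), len(space)))
    for tid, lab, freq in zip(
        df["target_id"].astype(str), df["label"].astype(str), df["frequency"].astype(float)
    ):
        P[pos[tid], index[lab]] = freq
    return ids, P


def write_attention_profile(profile: np.ndarray, path: str | Path) -> None:
    """Profile TSV: 1-based token position, mean attention score."""
    with open(path, "w") as fh:
        fh.write("position\tattention\n")
        for t, a in enumerate(np.asarray(profile, float), start=1):
            fh.write(f"{t}\t{a:.9e}\n")


# ---------------------------------------------------------------------------
# Embedding persistence


def save_embedding_tsv(embedder: GloveEmbedder, path: str | Path) -> None:
    """Embedding dictionary as TSV keyed ``kmer@position``."""
    with open(path, "w") as fh:
        header = "\t".join(f"d{i}" for i in range(embedder.dim))
        fh.write(f"token\t{header}\n")
        for (kmer, pos), vec in zip(embedder.vocab_.entries, embedder.vectors_):
            vals = "\t".join(f"{v:.9e}" for v in vec)
            fh.write(f"{kmer}@{pos}\t{vals}\n")


def _embedder_state(embedder: GloveEmbedder) -> dict:
    return {
        "emb_vectors": embedder.vectors_,
        "emb_positional": embedder.positional_,
    }


def save_embedder(embedder: GloveEmbedder, path: str | Path) -> None:
    np.savez(
        path,
        **_embedder_state(embedder),
        emb_params=json.dumps(embedder.get_params()),
        emb_n_positions=embedder.n_positions_,
    )


def load_embedder(path: str | Path) -> GloveEmbedder:
    with np.load(path, allow_pickle=False) as z:
        params = json.loads(str(z["emb_params"]))
        emb = GloveEmbedder(**params)
        emb.n_positions_ = int(z["emb_n_positions"])
        emb.vocab_ = PositionedVocab(
            k=emb.k, n_positions=emb.n_positions_, positioned=emb.positioned
        )
        emb.vectors_ = z["emb_vectors"]
        emb.positional_ = z["emb_positional"]
    return emb


# ---------------------------------------------------------------------------
# Model checkpoints


def save_model(model: IndelOutcomePredictor, path: str | Path) -> None:
    """Versioned checkpoint directory: config.json + weights.npz + history.csv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    net = model.network_
    est_params = {k: v for k, v in model.get_params(deep=False).items() if k != "embedder"}
    config = {
        "schema_version": CHECKPOINT_SCHEMA,
        "estimator": est_params,
        "embedder": model.embedder_.get_params(),
        "network": {
            "input_dim": net.input_dim,
            "seq_len": net.seq_len,
            "n_classes": net.n_classes,
            "units": net.units,
            "attention_T": net.attention_T,
            "mlp_hidden": net.mlp_hidden,
            "dropout_p": net.dropout_p,
            "l1_lambda": net.l1_lambda,
            "activation": net.activation,
            "seed": net.seed,
        },
    }
    (path / "config.json").write_text(json.dumps(config, indent=2))
    arrays = {f"net_{k}": v for k, v in net.params.items()}
    arrays["running_mean"] = net.running_mean
    arrays["running_var"] = net.running_var
    arrays.update(_embedder_state(model.embedder_))
    arrays["emb_n_positions"] = np.array(model.embedder_.n_positions_)
    np.savez(path / "weights.npz", **arrays)
    model.history_.to_csv(path / "history.csv", index=False)


def load_model(path: str | Path) -> IndelOutcomePredictor:
    path = Path(path)
    config = json.loads((path / "config.json").read_text())
    if config.get("schema_version") != CHECKPOINT_SCHEMA:
        raise LabelError(f"unsupported checkpoint schema in {path}")
    model = IndelOutcomePredictor(**config["estimator"])
    emb = GloveEmbedder(**config["embedder"])
    net = ApindelNetwork(**config["network"])
    with np.load(path / "weights.npz", allow_pickle=False) as z:
        for k in net.params:
            net.params[k] = z[f"net_{k}"]
        net.running_mean = z["running_mean"]
        net.running_var = z["running_var"]
        emb.n_positions_ = int(z["emb_n_positions"])
        emb.vocab_ = PositionedVocab(
            k=emb.k, n_positions=emb.n_positions_, positioned=emb.positioned
        )
        emb.vectors_ = z["emb_vectors"]
        emb.positional_ = z["emb_positional"]
    model.embedder_ = emb
    model.network_ = net
    model.n_classes_ = net.n_classes
    history_path = path / "history.csv"
    if history_path.exists():
        model.history_ = pd.read_csv(history_path)
    return model


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """One documented configuration document for the whole pipeline.

    Sections map onto the module configurations; unknown keys are
    rejected so typos fail loudly.
    """

    seed: int = 0
    outdir: str = "apindel_run"
    simulate: SimConfig = field(default_factory=SimConfig)
    embedding: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "simulate": asdict(self.simulate),
            "embedding": dict(self.embedding),
            "network": dict(self.network),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_run_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {"seed", "outdir", "simulate", "embedding", "network"}
    unknown = set(doc) - known
    if unknown:
        raise LabelError(f"unknown config keys: {sorted(unknown)}")
    sim_doc = doc.get("simulate", {}) or {}
    sim_fields = set(SimConfig.__dataclass_fields__)
    bad = set(sim_doc) - sim_fields
    if bad:
        raise LabelError(f"unknown simulate keys: {sorted(bad)}")
    emb_doc = doc.get("embedding", {}) or {}
    bad = set(emb_doc) - set(GloveEmbedder().get_params())
    if bad:
        raise LabelError(f"unknown embedding keys: {sorted(bad)}")
    net_doc = doc.get("network", {}) or {}
    bad = set(net_doc) - set(IndelOutcomePredictor().get_params()) - {"seed"}
    if bad:
        raise LabelError(f"unknown network keys: {sorted(bad)}")
    return RunConfig(
        seed=int(doc.get("seed", 0)),
        outdir=str(doc.get("outdir", "apindel_run")),
        simulate=SimConfig(**sim_doc),
        embedding=emb_doc,
        network=net_doc,
    )


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping, for log lines."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
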
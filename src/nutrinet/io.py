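"""Delimited-text readers/writers, schema validation and run manifests.

Every table travels as a UTF-8 CSV with '.' as the decimal separator, one
file per table, under a dataset directory; the processing conventions are
a small YAML document.  Validation is collective: all violated invariants
are reported together, each item naming the table, constraint and
offending rows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import FoodSystemDataset
from .errors import DataError, ValidationError
from .foods import PRODUCTION_IDS, VEG_SUBGROUPS
from .supply_chain import N_STAGES, ProcessingSpec

#: table name -> required columns
SCHEMAS = {
    "production": ["crop", "region", "year", "tonnes"],
    "trade": ["crop", "year", "imports", "exports", "stock_change"],
    "use": ["crop", "year", "feed", "seed", "other"],
    "losses": ["id", "stage", "fraction"],
    "edible": ["form", "edible_proportion"],
    "veg_shares": ["subgroup", "share"],
    "composition": ["form", "nutrient", "content"],
    "members": ["group", "member", "nutrient", "content"],
    "population": ["region", "year", "population"],
    "structure": ["region", "year", "age_group", "sex", "proportion"],
    "dri": ["nutrient", "age_group", "sex", "reference", "value"],
    "animal_intake": ["food_group", "grams_per_capita_day"],
    "animal_composition": ["food_group", "nutrient", "content"],
}

PROCESSING_FILE = "processing.yaml"


def write_dataset(data: FoodSystemDataset, directory: str | Path) -> Path:
    """Write every table of *data* as CSV plus the processing YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in SCHEMAS:
        getattr(data, name).to_csv(directory / f"{name}.csv", index=False)
    spec = data.processing
    doc = {
        "wholegrain_fraction": spec.wholegrain_fraction,
        "food_oil_fraction": spec.food_oil_fraction,
        "extraction_rate": spec.extraction_rate,
        "shelling_rate": spec.shelling_rate,
        "form_edible": spec.form_edible,
        "retention": None
        if spec.retention is None
        else [{"form": f, "nutrient": n, "factor": v} for (f, n), v in spec.retention.items()],
    }
    with open(directory / PROCESSING_FILE, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return directory


def read_dataset(directory: str | Path, validate: bool = True) -> FoodSystemDataset:
    """Load a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    tables = {}
    for name, columns in SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise DataError(f"missing table file {path}")
        frame = pd.read_csv(path)
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            raise DataError(f"{path.name}: missing columns {missing}")
        tables[name] = frame[columns]
    spec_path = directory / PROCESSING_FILE
    if spec_path.exists():
        with open(spec_path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        retention = doc.get("retention")
        processing = ProcessingSpec(
            wholegrain_fraction=doc.get("wholegrain_fraction") or {},
            food_oil_fraction=doc.get("food_oil_fraction") or {},
            extraction_rate=doc.get("extraction_rate") or {},
            shelling_rate=doc.get("shelling_rate") or {},
            form_edible=doc.get("form_edible") or {},
            retention=None
            if not retention
            else {(r["form"], r["nutrient"]): float(r["factor"]) for r in retention},
        )
    else:
        processing = ProcessingSpec()
    data = FoodSystemDataset(processing=processing, **tables)
    if validate:
        validate_dataset(data)
    return data


def validate_dataset(data: FoodSystemDataset) -> None:
    """Assert the cross-table invariants; raise ValidationError listing all failures."""
    problems: list[str] = []

    neg = data.production[data.production["tonnes"] < 0]
    for row in neg.itertuples():
        problems.append(f"production: negative tonnage for {row.crop}/{row.region}/{row.year}")
    present = set(data.production["crop"].unique())
    for crop in PRODUCTION_IDS:
        if crop not in present:
            problems.append(f"production: crop {crop!r} missing entirely")

    bad_losses = data.losses[(data.losses["fraction"] < 0) | (data.losses["fraction"] >= 1)]
    for row in bad_losses.itertuples():
        problems.append(f"losses: fraction {row.fraction} outside [0,1) for {row.id} stage {row.stage}")
    counts = data.losses.groupby("id")["stage"].count()
    for identifier, n in counts.items():
        if n != N_STAGES:
            problems.append(f"losses: {identifier} has {n} stage rows, expected {N_STAGES}")

    bad_alpha = data.edible[
        (data.edible["edible_proportion"] <= 0) | (data.edible["edible_proportion"] > 1)
    ]
    for row in bad_alpha.itertuples():
        problems.append(f"edible: proportion {row.edible_proportion} outside (0,1] for {row.form}")

    share_sum = float(data.veg_shares["share"].sum())
    if abs(share_sum - 1.0) > 1e-6:
        problems.append(f"veg_shares: shares sum to {share_sum:.6f}, expected 1 within 1e-6")
    if sorted(data.veg_shares["subgroup"]) != sorted(VEG_SUBGROUPS):
        problems.append("veg_shares: must list exactly the seven vegetable subgroups")

    if (data.composition["content"] < 0).any():
        problems.append("composition: negative nutrient contents present")

    sums = data.structure.groupby(["region", "year"])["proportion"].sum()
    for (region, year), total in sums.items():
        if abs(total - 1.0) > 1e-9:
            problems.append(
                f"structure: proportions for {region}/{year} sum to {total!r}, expected 1"
            )
    if (data.population["population"] <= 0).any():
        problems.append("population: non-positive totals present")

    wide = data.dri.pivot_table(
        index=["nutrient", "age_group", "sex"], columns="reference", values="value"
    )
    if {"EAR", "RNI"} <= set(wide.columns):
        both = wide.dropna(subset=["EAR", "RNI"])
        bad = both[both["EAR"] > both["RNI"]]
        for idx in bad.index:
            problems.append(f"dri: EAR exceeds RNI for {idx}")
    if (data.dri["value"] <= 0).any():
        problems.append("dri: non-positive reference values present")

    if (data.animal_intake["grams_per_capita_day"] < 0).any():
        problems.append("animal_intake: negative intakes present")

    if problems:
        raise ValidationError(problems)


@dataclass
class RunManifest:
    """Provenance record written next to every output table."""

    command: str
    seed: int | None
    config: dict
    input_digests: dict[str, str]
    version: str
    timestamp: str

    @property
    def manifest_id(self) -> str:
        payload = json.dumps(
            {"command": self.command, "seed": self.seed, "config": self.config,
             "inputs": self.input_digests},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, directory: str | Path) -> Path:
        path = Path(directory) / "manifest.json"
        doc = asdict(self)
        doc["manifest_id"] = self.manifest_id
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
        return path


def build_manifest(command: str, seed: int | None, config: dict, inputs: dict[str, Path]) -> RunManifest:
    from . import __version__

    digests = {}
    for name, path in inputs.items():
        path = Path(path)
        if path.is_file():
            digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        elif path.is_dir():
            for child in sorted(path.glob("*.csv")) + sorted(path.glob("*.yaml")):
                digests[f"{name}/{child.name}"] = hashlib.sha256(child.read_bytes()).hexdigest()[:16]
    return RunManifest(
        command=command,
        seed=seed,
        config=_jsonable(config),
        input_digests=digests,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
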
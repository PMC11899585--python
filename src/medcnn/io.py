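"""Reading real datasets and writing fixtures / reports.

Expected on-disk layout (TSV or CSV, sniffed from the extension):

* feature table — rows = samples, first column ``sample_id``, remaining
  header = feature ids;
* phenotype table — columns ``sample_id``, ``exposure`` (0/1 or any
  two-level coding), ``outcome`` (continuous);
* network map — two columns ``feature_id``, ``network``.

Samples are aligned by id across the three files; features missing from
the map fall into the ``other`` bucket with a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GeneratedDataset, MediationDataset, SimulationConfig

logger = logging.getLogger(__name__)

OTHER_LABEL = "other"


@dataclass
class NetworkMap:
    """feature id -> network label, with networks in a fixed order and any
    unmapped features collected under ``other`` (always last)."""

    assignment: dict[str, str]
    networks: list[str]

    def __post_init__(self) -> None:
        missing = set(self.assignment.values()) - set(self.networks)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not in network list")


def _read_table(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, **kw)


def build_network_map(taxonomy: pd.DataFrame, top_k: int = 3) -> NetworkMap:
    """Group features by their taxonomy label, keeping the ``top_k`` most
    populous labels as named networks and merging the rest into ``other``.
    Ties in the feature counts are broken alphabetically."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if taxonomy.empty:
        raise ValueError("empty taxonomy table")
    tax = taxonomy.iloc[:, :2].copy()
    tax.columns = ["feature_id", "network"]
    counts = tax.groupby("network").size().reset_index(name="n")
    counts = counts.sort_values(["n", "network"], ascending=[False, True])
    top = counts["network"].head(top_k).tolist()
    assignment = {}
    has_other = False
    for fid, net in zip(tax["feature_id"], tax["network"]):
        if net in top:
            assignment[str(fid)] = str(net)
        else:
            assignment[str(fid)] = OTHER_LABEL
            has_other = True
    networks = top + ([OTHER_LABEL] if has_other else [])
    return NetworkMap(assignment=assignment, networks=networks)


def read_dataset(
    features_path: str | Path,
    phenotype_path: str | Path,
    network_map_path: str | Path,
) -> MediationDataset:
    """Load and align a real study from the three on-disk tables."""
    feat = _read_table(features_path)
    phen = _read_table(phenotype_path)
    nmap = _read_table(network_map_path, header=None, comment="#")
    if nmap.iloc[0, 0] in ("feature_id", "feature"):
        nmap = nmap.iloc[1:]
    nmap.columns = ["feature_id", "network"][: nmap.shape[1]]

    for col in ("sample_id", "exposure", "outcome"):
        if col not in phen.columns:
            raise ValueError(f"phenotype table lacks required column {col!r}")
    feat = feat.rename(columns={feat.columns[0]: "sample_id"})
    for name, df in (("feature", feat), ("phenotype", phen)):
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicated sample id(s) in {name} table: {dups}")

    ids_f = set(feat["sample_id"].astype(str))
    ids_p = set(phen["sample_id"].astype(str))
    if ids_f != ids_p:
        diff = sorted(ids_f ^ ids_p)
        raise ValueError(f"sample ids differ between tables: {diff}")

    feat = feat.set_index(feat["sample_id"].astype(str)).drop(columns="sample_id")
    phen = phen.set_index(phen["sample_id"].astype(str))
    order = sorted(ids_f)
    feat, phen = feat.loc[order], phen.loc[order]

    if feat.isna().any().any() or phen[["exposure", "outcome"]].isna().any().any():
        raise ValueError("missing values present; no imputation is performed")

    exposure = phen["exposure"]
    levels = sorted(exposure.astype(str).unique())
    if set(levels) <= {"0", "1"}:
        A = exposure.astype(int).to_numpy()
    elif len(levels) == 2:
        A = (exposure.astype(str) == levels[1]).astype(int).to_numpy()
        logger.info("exposure coded %s -> 0, %s -> 1", levels[0], levels[1])
    else:
        raise ValueError(f"exposure is not binary: levels {levels}")
    Y = phen["outcome"].astype(float).to_numpy()

    assignment = dict(zip(nmap["feature_id"].astype(str),
                          nmap["network"].astype(str)))
    networks: list[str] = []
    for fid in feat.columns:
        net = assignment.get(str(fid))
        if net is None:
            logger.warning("feature %s absent from network map; assigned to "
                           "'%s'", fid, OTHER_LABEL)
            assignment[str(fid)] = OTHER_LABEL
            net = OTHER_LABEL
        if net not in networks:
            networks.append(net)
    if OTHER_LABEL in networks:  # keep the catch-all bucket last
        networks = [n for n in networks if n != OTHER_LABEL] + [OTHER_LABEL]

    Z, feature_labels = [], []
    for net in networks:
        cols = [c for c in feat.columns if assignment[str(c)] == net]
        Z.append(feat[cols].to_numpy(dtype=float))
        feature_labels.append(cols)
    return MediationDataset(A=A, Y=Y, Z=Z, sample_ids=order,
                            network_labels=networks,
                            feature_labels=feature_labels)


def write_dataset(dataset: MediationDataset, out_dir: str | Path,
                  prefix: str = "dataset") -> dict[str, Path]:
    """Write a dataset as the three TSV tables read_dataset expects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = dataset.n
    ids = list(dataset.sample_ids) if dataset.sample_ids is not None else [
        f"S{i:05d}" for i in range(n)
    ]
    nets = (list(dataset.network_labels)
            if dataset.network_labels is not None
            else [f"net{k+1}" for k in range(len(dataset.Z))])
    labels = (dataset.feature_labels
              if dataset.feature_labels is not None
              else [[f"{nets[k]}_f{j+1}" for j in range(z.shape[1])]
                    for k, z in enumerate(dataset.Z)])

    feat = pd.DataFrame(np.concatenate(dataset.Z, axis=1),
                        columns=[c for cols in labels for c in cols])
    feat.insert(0, "sample_id", ids)
    phen = pd.DataFrame({"sample_id": ids, "exposure": dataset.A,
                         "outcome": dataset.Y})
    nmap = pd.DataFrame({
        "feature_id": [c for cols in labels for c in cols],
        "network": [nets[k] for k, cols in enumerate(labels) for _ in cols],
    })
    paths = {
        "features": out_dir / f"{prefix}_features.tsv",
        "phenotype": out_dir / f"{prefix}_phenotype.tsv",
        "network_map": out_dir / f"{prefix}_network_map.tsv",
    }
    feat.to_csv(paths["features"], sep="\t", index=False)
    phen.to_csv(paths["phenotype"], sep="\t", index=False)
    nmap.to_csv(paths["network_map"], sep="\t", index=False, header=False)
    if isinstance(dataset, GeneratedDataset) and dataset.config is not None:
        meta = paths["meta"] = out_dir / f"{prefix}_config.json"
        meta.write_text(json.dumps(config_to_dict(dataset.config), indent=2))
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    d = {k: getattr(config, k) for k in (
        "scenario", "alpha0", "alpha1", "alpha2", "beta0", "beta1",
        "sigma_M", "sigma_Y", "n", "feature_map", "interactions",
        "interaction_interval", "interaction_strength", "seed",
    )}
    d["network_sizes"] = list(config.network_sizes)
    return d
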
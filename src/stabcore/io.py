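"""Readers and writers for the pipeline's plain-text formats.

Everything is tab-separated with ``#`` comment lines; floats are serialized
with 6 significant digits so outputs are diff-able and byte-stable across
identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .circuits import ElementaryCircuit
from .contextualize import ContextualizationResult
from .dynamics import Attractor, BooleanState, PartialState
from .network import SignedNetwork, sign_to_word, word_to_sign
from .omics import DECall, ExpressionMatrix, IntegratedCall

log = logging.getLogger("stabcore")

FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# signed networks (3-column TSV / SIF dialect)


def read_signed_network(path: str | Path) -> SignedNetwork:
    """Parse ``source<TAB>activates|inhibits<TAB>target`` (SIF dialect accepted).

    Lines starting with ``#`` are comments; duplicate triples collapse with
    a logged warning; any other relation token is a parse error naming the
    line.
    """
    path = Path(path)
    edges = []
    seen = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 fields (source, relation, target)"
                )
            src, rel, tgt = parts
            try:
                sign = word_to_sign(rel)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
            triple = (src, tgt, sign)
            if triple in seen:
                log.warning("%s:%d: duplicate edge %s -> %s ignored", path, lineno, src, tgt)
                continue
            seen.add(triple)
            edges.append(triple)
    return SignedNetwork.from_edges(edges)


def write_signed_network(net: SignedNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for src, tgt, sign in sorted(net.edges):
            fh.write(f"{src}\t{sign_to_word(sign)}\t{tgt}\n")


# ---------------------------------------------------------------------------
# Boolean states


def read_state(path: str | Path) -> dict[str, int | None]:
    """Two-column TSV ``gene<TAB>0|1|NA``; NA marks an unknown value."""
    path = Path(path)
    values: dict[str, int | None] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields (gene, value)")
            gene, val = parts
            if val == "NA":
                values[gene] = None
            elif val in ("0", "1"):
                values[gene] = int(val)
            else:
                raise ValueError(f"{path}:{lineno}: state value must be 0, 1 or NA")
    if not values:
        raise ValueError(f"{path}: empty state file")
    return values


def to_boolean_state(net: SignedNetwork, values: Mapping[str, int | None]) -> BooleanState:
    known = {g: v for g, v in values.items() if v is not None}
    return BooleanState.from_mapping(net, known)


def to_partial_state(values: Mapping[str, int | None]) -> PartialState:
    return PartialState(dict(values))


def write_state(values: Mapping[str, int | None], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in sorted(values):
            v = values[gene]
            fh.write(f"{gene}\t{'NA' if v is None else v}\n")


# ---------------------------------------------------------------------------
# expression / design / methylation tables


def read_expression(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Expression TSV (first column gene, header sample ids) + design file.

    The design is a 2-column TSV ``sample<TAB>cell_type`` or a YAML mapping.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    design = read_design(design_path)
    return ExpressionMatrix(values, design)


def read_design(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        with path.open() as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: design YAML must map sample -> cell type")
        return {str(k): str(v) for k, v in data.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "cell_type"], comment="#")
    return dict(zip(df["sample"].astype(str), df["cell_type"].astype(str)))


def write_expression(mat: ExpressionMatrix, path: str | Path, design_path: str | Path) -> None:
    mat.values.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    with Path(design_path).open("w") as fh:
        for s in mat.values.columns:
            fh.write(f"{s}\t{mat.design[s]}\n")


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    """Per-cell-type TSV ``chrom pos strand meth_count total_count``."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "pos", "strand", "meth_count", "total_count"],
        header=None,
        dtype={"chrom": str, "pos": int, "strand": str, "meth_count": int, "total_count": int},
    )
    return df


def write_methylation_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "pos", "strand", "meth_count", "total_count"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# stage outputs


def write_de_calls(calls: Iterable[DECall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tlog2fc_vs_ref1\tlog2fc_vs_ref2\tp_value\tdirection\n")
        for c in calls:
            fh.write(
                f"{c.gene}\t{_fmt(c.log2fc_vs_ref1)}\t{_fmt(c.log2fc_vs_ref2)}\t"
                f"{_fmt(c.p_value)}\t{c.direction}\n"
            )


def write_integrated_calls(calls: Iterable[IntegratedCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tmeth_delta_vs_ref1\tmeth_delta_vs_ref2\tde_direction\tcategory\n")
        for c in calls:
            fh.write(
                f"{c.gene}\t{_fmt(c.meth_delta_vs_ref1)}\t{_fmt(c.meth_delta_vs_ref2)}\t"
                f"{c.de_direction}\t{c.category}\n"
            )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def write_circuits(circuits: Iterable[ElementaryCircuit], path: str | Path) -> None:
    """``circuit_id<TAB>length<TAB>sign<TAB>node1|node2|...``"""
    with Path(path).open("w") as fh:
        fh.write("circuit_id\tlength\tsign\tnodes\n")
        for i, c in enumerate(circuits):
            fh.write(f"c{i:05d}\t{c.length}\t{c.sign:+d}\t{'|'.join(c.nodes)}\n")


def write_attractors(attractors: Iterable[Attractor], path: str | Path) -> None:
    """One row per attractor state: attractor id, length, basin, step, state bits."""
    attractors = sorted(attractors, key=lambda a: a.states[0].code)
    with Path(path).open("w") as fh:
        fh.write("attractor_id\tlength\tbasin_size\tstep\tstate\n")
        for i, a in enumerate(attractors):
            basin = "" if a.basin_size is None else str(a.basin_size)
            for j, s in enumerate(a.states):
                bits = "".join(str((s.code >> k) & 1) for k in range(len(s.genes)))
                fh.write(f"a{i:03d}\t{a.length}\t{basin}\t{j}\t{bits}\n")


def write_contextualization(result: ContextualizationResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_signed_network(result.best_network, outdir / "best_network.sif")
    with (outdir / "core.tsv").open("w") as fh:
        fh.write("component_id\tgene\n")
        for i, comp in enumerate(result.core.components):
            for g in sorted(comp):
                fh.write(f"scc{i}\t{g}\n")
    write_attractors(result.attractors, outdir / "attractors.tsv")
    with (outdir / "fitness_trace.tsv").open("w") as fh:
        fh.write("generation\tbest\tmean\n")
        for g, (b, m) in enumerate(result.fitness_trace):
            fh.write(f"{g}\t{_fmt(b)}\t{_fmt(m)}\n")


# ---------------------------------------------------------------------------
# run manifest


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)
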
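"""Readers and writers for the pipeline's plain-text interchange formats.

Matrices are TSV with the analyte key in the first column and sample ids in
the header (phospho keys serialized as ``gene|accession|residue|position``);
prior networks use a SIGNOR-like TSV dialect (ENTITYA, ENTITYB, EFFECT,
MECHANISM, RESIDUE, DIRECT); patient models round-trip as SIF plus a
node-attribute TSV, or GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO

from .activity import MutationCall, Regulon
from .harmonize import OmicsMatrix
from .network import CausalEdge, PKN, PatientNetwork


def read_omics_tsv(path, omic_kind: str, stage: str = "raw") -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix(df, omic_kind, stage)


def write_omics_tsv(m: OmicsMatrix, path) -> None:
    m.data.to_csv(path, sep="\t")


def read_fasta(path) -> dict:
    """Accession -> sequence from a FASTA file (first token of the header)."""
    return {rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(path), "fasta")}


def read_regulons(path) -> list[Regulon]:
    """TSV columns: regulator, layer, target, mode, weight."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for (reg, layer), grp in df.groupby(["regulator", "layer"], sort=True):
        targets = tuple(
            (r.target, int(r.mode), float(r.weight)) for r in grp.itertuples()
        )
        out.append(Regulon(reg, layer, targets))
    return out


def read_mutations(path) -> list[MutationCall]:
    df = pd.read_csv(path, sep="\t")
    return [MutationCall(str(r.patient), str(r.gene), int(r.effect)) for r in df.itertuples()]


def read_pkn_tsv(path) -> PKN:
    """SIGNOR-like dialect: ENTITYA, ENTITYB, EFFECT(activation|inhibition),
    MECHANISM, RESIDUE, DIRECT(YES|NO)."""
    df = pd.read_csv(path, sep="\t")
    edges = []
    for r in df.itertuples():
        effect = str(r.EFFECT).strip().lower()
        if effect not in ("activation", "inhibition"):
            raise ValueError(f"unknown EFFECT {r.EFFECT!r}")
        edges.append(
            CausalEdge(
                source=str(r.ENTITYA),
                target=str(r.ENTITYB),
                sign=1 if effect == "activation" else -1,
                direct=str(getattr(r, "DIRECT", "YES")).strip().upper() == "YES",
                mechanism=_opt(getattr(r, "MECHANISM", None)),
                residue=_opt(getattr(r, "RESIDUE", None)),
            )
        )
    return PKN(edges)


def write_pkn_tsv(pkn: PKN, path) -> None:
    rows = [
        {
            "ENTITYA": e.source,
            "ENTITYB": e.target,
            "EFFECT": "activation" if e.sign == 1 else "inhibition",
            "MECHANISM": e.mechanism or "",
            "RESIDUE": e.residue or "",
            "DIRECT": "YES" if e.direct else "NO",
        }
        for e in pkn.edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _opt(v):
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return str(v)


def write_patient_network(net: PatientNetwork, prefix) -> None:
    """SIF + node-attribute TSV + GraphML export of one patient model."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".sif"), "w") as fh:
        for s, t, sign in net.edges:
            rel = "activation" if sign == 1 else "inhibition"
            fh.write(f"{s}\t{rel}\t{t}\n")
    attrs = pd.DataFrame(
        [{"gene": g, "state": s, "is_source": g in net.sources} for g, s in sorted(net.states.items())]
    )
    attrs.to_csv(prefix.with_suffix(".nodes.tsv"), sep="\t", index=False)
    g = nx.DiGraph(patient=net.patient)
    for gene, s in net.states.items():
        g.add_node(gene, state=int(s), is_source=bool(gene in net.sources))
    for s, t, sign in net.edges:
        g.add_edge(s, t, sign=int(sign))
    nx.write_graphml(g, prefix.with_suffix(".graphml"))


def read_patient_network(prefix, patient: str) -> PatientNetwork:
    prefix = Path(prefix)
    edges = []
    with open(prefix.with_suffix(".sif")) as fh:
        for line in fh:
            s, rel, t = line.rstrip("\n").split("\t")
            edges.append((s, t, 1 if rel == "activation" else -1))
    attrs = pd.read_csv(prefix.with_suffix(".nodes.tsv"), sep="\t")
    states = {str(r.gene): int(r.state) for r in attrs.itertuples()}
    sources = {str(r.gene) for r in attrs.itertuples() if bool(r.is_source)}
    return PatientNetwork(patient=patient, states=states, edges=sorted(edges), sources=sources)


def write_json_report(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(v):
    try:
        return v.item()
    except AttributeError:
        return str(v)
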
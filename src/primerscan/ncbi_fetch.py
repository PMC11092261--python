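"""Batched retrieval of nucleotide sequences + taxonomy by accession id.

Network access is isolated behind a transport object so the module is fully
unit-testable offline: a transport implements ``get_sequences(ids)`` and
``get_taxonomy(ids)``; the shipped :class:`EntrezTransport` talks to the
NCBI E-utilities nucleotide endpoints, while tests inject in-memory stubs.
Failed ids are reported, never silently dropped, and output order always
follows input order regardless of batch boundaries.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Transport",
    "FetchJob",
    "FetchReport",
    "EntrezTransport",
    "plan_batches",
    "fetch_job",
]


class Transport(Protocol):
    def get_sequences(self, ids: Sequence[str]) -> dict:
        """id -> (description, sequence); missing ids simply absent."""

    def get_taxonomy(self, ids: Sequence[str]) -> dict:
        """id -> list of (rank, taxon) tuples."""


@dataclass
class FetchJob:
    ids: Sequence[str]
    out_fasta: Path
    batch_size: int = 100
    retrieve_taxonomy: bool = False
    tax_path: Optional[Path] = None
    max_attempts: int = 3
    backoff_seconds: float = 0.4
    inter_batch_delay: float = 0.4


@dataclass
class FetchReport:
    n_requested: int
    n_written: int
    failed_ids: list = field(default_factory=list)


def plan_batches(ids: Sequence[str], batch_size: int) -> list:
    """Deduplicate (order-preserving) then split into consecutive batches."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    seen: set = set()
    unique = []
    for i in ids:
        if i not in seen:
            seen.add(i)
            unique.append(i)
    if len(unique) < len(ids):
        logger.info("deduplicated %d repeated id(s)", len(ids) - len(unique))
    return [unique[i : i + batch_size] for i in range(0, len(unique), batch_size)]


def _with_retries(fn, batch, max_attempts, backoff):
    last_err = None
    for attempt in range(max_attempts):
        try:
            return fn(batch)
        except Exception as err:  # transport failures are retryable
            last_err = err
            logger.warning(
                "batch attempt %d/%d failed: %s", attempt + 1, max_attempts, err
            )
            if attempt + 1 < max_attempts and backoff > 0:
                time.sleep(backoff * (attempt + 1))
    raise last_err


def fetch_job(job: FetchJob, transport: Transport) -> FetchReport:
    """Run one download job through the given transport.

    Writes FASTA records (and optionally an ``id<TAB>lineage;`` taxonomy
    file) in input-id order. Ids that fail after retries land in the report;
    if every batch fails the whole job raises.
    """
    batches = plan_batches(job.ids, job.batch_size)
    if not batches:
        raise ValueError("no accession ids to fetch")

    sequences: dict = {}
    taxonomies: dict = {}
    failed: list = []
    any_batch_ok = False
    for k, batch in enumerate(batches):
        if k and job.inter_batch_delay > 0:
            time.sleep(job.inter_batch_delay)
        try:
            got = _with_retries(
                transport.get_sequences, batch, job.max_attempts, job.backoff_seconds
            )
        except Exception:
            failed.extend(batch)
            continue
        any_batch_ok = True
        sequences.update(got)
        failed.extend(i for i in batch if i not in got)
        if job.retrieve_taxonomy:
            try:
                taxonomies.update(
                    _with_retries(
                        transport.get_taxonomy,
                        [i for i in batch if i in got],
                        job.max_attempts,
                        job.backoff_seconds,
                    )
                )
            except Exception:
                logger.warning("taxonomy retrieval failed for one batch")

    if not any_batch_ok:
        raise RuntimeError("all batches failed; nothing downloaded")

    ordered = [i for batch in batches for i in batch if i in sequences]
    with open(job.out_fasta, "wt") as out:
        for rid in ordered:
            desc, seq = sequences[rid]
            header = f">{rid} {desc}".rstrip()
            out.write(f"{header}\n{seq}\n")

    if job.retrieve_taxonomy:
        tax_path = job.tax_path or Path(job.out_fasta).with_suffix(".tax")
        with open(tax_path, "wt") as out:
            for rid in ordered:
                ranks = taxonomies.get(rid)
                if ranks is None:
                    continue
                out.write(rid + "\t" + ";".join(t for _, t in ranks) + ";\n")

    if failed:
        logger.warning("%d id(s) failed: %s", len(failed), ", ".join(failed))
    return FetchReport(
        n_requested=sum(len(b) for b in batches),
        n_written=len(ordered),
        failed_ids=failed,
    )


class EntrezTransport:
    """Live transport for the NCBI E-utilities nucleotide endpoints.

    Requires a contact e-mail per NCBI usage policy; an API key raises the
    permitted request rate. Only exercised by opt-in integration tests —
    the offline suite uses stub transports.
    """

    EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"

    def __init__(self, email: str, api_key: Optional[str] = None, timeout: float = 60.0):
        if not email:
            raise ValueError("a contact e-mail is required for NCBI requests")
        self.email = email
        self.api_key = api_key
        self.timeout = timeout

    def _params(self, **kw):
        p = {"email": self.email, "tool": "primerscan", **kw}
        if self.api_key:
            p["api_key"] = self.api_key
        return p

    def get_sequences(self, ids: Sequence[str]) -> dict:
        import requests
        from io import StringIO

        from Bio import SeqIO

        resp = requests.get(
            f"{self.EUTILS}/efetch.fcgi",
            params=self._params(
                db="nucleotide", id=",".join(ids), rettype="fasta", retmode="text"
            ),
            timeout=self.timeout,
        )
        resp.raise_for_status()
        out = {}
        for rec in SeqIO.parse(StringIO(resp.text), "fasta"):
            # efetch echoes versioned accessions; index by requested id too
            out[rec.id] = (rec.description.partition(" ")[2], str(rec.seq).upper())
        for rid in ids:
            bare = rid.split(".", 1)[0]
            for key in list(out):
                if key.split(".", 1)[0] == bare and rid not in out:
                    out[rid] = out[key]
        return {rid: out[rid] for rid in ids if rid in out}

    def get_taxonomy(self, ids: Sequence[str]) -> dict:
        import requests
        import xml.etree.ElementTree as ET

        resp = requests.get(
            f"{self.EUTILS}/efetch.fcgi",
            params=self._params(
                db="nucleotide", id=",".join(ids), rettype="gb", retmode="xml"
            ),
            timeout=self.timeout,
        )
        resp.raise_for_status()
        root = ET.fromstring(resp.text)
        out = {}
        for gbseq in root.iter("GBSeq"):
            acc = gbseq.findtext("GBSeq_accession-version", "")
            taxonomy = gbseq.findtext("GBSeq_taxonomy", "")
            organism = gbseq.findtext("GBSeq_organism", "")
            levels = [t.strip() for t in taxonomy.split(";") if t.strip()]
            if organism:
                levels.append(organism)
            for rid in ids:
                if rid.split(".", 1)[0] == acc.split(".", 1)[0]:
                    out[rid] = [(f"level_{i+1}", t) for i, t in enumerate(levels)]
        return out
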
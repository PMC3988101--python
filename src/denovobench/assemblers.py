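"""Assembler hooks: built-in stubs and external command templates.

Real assemblers (Trinity, Velvet/Oases) are external programs; the pipeline
invokes them through a shell command template with ``{reads1}``, ``{reads2}``,
``{out_fasta}`` and ``{workdir}`` placeholders.  For testing without any
external binary, reference-peeking stub assemblers produce assemblies with
known, exactly predictable evaluation outcomes:

* ``identity`` — emits the reference transcripts verbatim (perfect assembly);
* ``truncate:F`` — emits each reference with the last fraction F removed
  (nothing is full-length, but nothing is a false positive for F < 0.5);
* ``chimera`` — fuses the first half of each transcript with the second
  half of the next one (gene-fusion-style misassemblies).

Documented presets record the command lines the benchmarked assemblers are
conventionally run with; none is required at test scale.
"""

from __future__ import annotations

import shlex
import subprocess
from pathlib import Path
from typing import Callable, Protocol

from .transcriptome import TranscriptSet, load_reference_transcripts

# Conventional full-scale invocations (documentation only; nothing bundled).
ASSEMBLER_PRESETS = {
    "trinity": "Trinity --seqType fq --left {reads1} --right {reads2} "
    "--CPU 6 --bflyHeapSpaceMax 10G --bflyGCThreads 4 --output {workdir}",
    "velvet": "velveth {workdir} 25 -fastq -shortPaired {reads1} {reads2} "
    "&& velvetg {workdir} -read_trkg yes -ins_length 200",
    "oases": "oases {workdir} -min_trans_lgth 200",
}


class AssemblerHook(Protocol):
    def __call__(
        self, reference: TranscriptSet, reads1: Path | None, reads2: Path | None, workdir: Path
    ) -> TranscriptSet: ...


def identity_assembler(
    reference: TranscriptSet, reads1=None, reads2=None, workdir=None
) -> TranscriptSet:
    out = TranscriptSet()
    for i, (tid, seq, _) in enumerate(reference.items()):
        out.add(f"asm_{i:05d}", seq)
    return out


def make_truncating_assembler(drop_fraction: float = 0.4) -> AssemblerHook:
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in (0, 1)")

    def assemble(reference, reads1=None, reads2=None, workdir=None) -> TranscriptSet:
        out = TranscriptSet()
        for i, (tid, seq, _) in enumerate(reference.items()):
            keep = max(1, int(len(seq) * (1.0 - drop_fraction)))
            out.add(f"asm_{i:05d}", seq[:keep])
        return out

    return assemble


def chimera_assembler(
    reference: TranscriptSet, reads1=None, reads2=None, workdir=None
) -> TranscriptSet:
    ids = sorted(reference.ids())
    out = TranscriptSet()
    for i, tid in enumerate(ids):
        a = reference.sequence(tid)
        b = reference.sequence(ids[(i + 1) % len(ids)])
        out.add(f"asm_{i:05d}", a[: len(a) // 2] + b[len(b) // 2 :])
    return out


def get_stub_assembler(spec: str) -> AssemblerHook:
    """Resolve a ``stub:NAME[:PARAM]`` spec to a callable hook."""
    parts = spec.split(":")
    if parts[0] == "stub":
        parts = parts[1:]
    name = parts[0]
    if name == "identity":
        return identity_assembler
    if name == "truncate":
        frac = float(parts[1]) if len(parts) > 1 else 0.4
        return make_truncating_assembler(frac)
    if name == "chimera":
        return chimera_assembler
    raise ValueError(f"unknown stub assembler: {name!r}")


class ExternalAssemblerError(RuntimeError):
    def __init__(self, command: str, returncode: int):
        self.command = command
        self.returncode = returncode
        super().__init__(f"assembler exited with status {returncode}: {command}")


def run_external_assembler(
    template: str, reads1: Path, reads2: Path, workdir: Path
) -> TranscriptSet:
    """Run a templated shell command and load the FASTA it produces.

    The template must contain ``{out_fasta}`` (or write to
    ``<workdir>/assembly.fasta``); a non-zero exit raises
    :class:`ExternalAssemblerError` so the pipeline can record a failure row
    and continue.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    out_fasta = workdir / "assembly.fasta"
    command = template.format(
        reads1=shlex.quote(str(reads1)),
        reads2=shlex.quote(str(reads2)),
        out_fasta=shlex.quote(str(out_fasta)),
        workdir=shlex.quote(str(workdir)),
    )
    proc = subprocess.run(command, shell=True, cwd=workdir)
    if proc.returncode != 0:
        raise ExternalAssemblerError(command, proc.returncode)
    return load_reference_transcripts(out_fasta)


def resolve_assembler(spec: str | AssemblerHook | None):
    """Accept a callable hook, a ``stub:...`` spec, or a shell template."""
    if spec is None or callable(spec):
        return spec
    if spec.startswith("stub:") or spec in ("identity", "truncate", "chimera"):
        return get_stub_assembler(spec)

    def assemble(reference, reads1, reads2, workdir):
        return run_external_assembler(spec, reads1, reads2, workdir)

    return assemble
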
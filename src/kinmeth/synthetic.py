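"""Seeded generator of paired native/WGA aligned-kinetics datasets.

The generative model mirrors how SMRT sequencing produces kinetic data:

* a circularized insert is sampled uniformly from the reference; the
  polymerase read length fixes how many passes (subreads) it completes,
  alternating strands each pass — short inserts yield many passes (high
  single-molecule coverage), long inserts one or two;
* each emitted base's log IPD is the sum of a fixed per-(strand, position)
  sequence-context offset (shared between the native sample and its WGA
  twin, which is exactly the bias the WGA subtraction removes), a
  per-molecule polymerase-speed offset, a methylation shift ``delta`` at
  modified motif positions, and i.i.d. Gaussian noise;
* alignment errors (mismatch / insertion / deletion, equal shares) are
  injected at a configurable rate and perturb events but never the truth;
* methylation regimes encode the biological scenarios of interest:
  ``constitutive`` (every site methylated), ``phase_variable`` (a fraction
  of molecules fully methylated, the rest untouched — an MTase switching
  on/off between cells) and ``stochastic`` (each site independently
  methylated with probability ``p_site`` — a processivity-limited MTase).

A WGA dataset forces ``delta = 0`` and all truth flags false.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .motif import MotifSpec, find_motif_sites
from .records import FORWARD, REVERSE, KineticsDataset, NULL_POS, SubreadRecord

log = logging.getLogger(__name__)

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
_ROLE = {"native": 0, "wga": 1}

REGIMES = ("constitutive", "phase_variable", "stochastic")


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    ``delta`` defaults to 2.0 natural-log units, the location of the
    methylated 6mA score component; ``noise_sd`` (per-pass log-IPD noise)
    of 1.2 puts the SM_SN standard deviation near 0.5 at a single-molecule
    coverage around 10, ``context_sd`` of 0.4 gives realistic
    position-to-position kinetic baselines, and the default 8 kb polymerase
    read over ~250 bp inserts yields the many-pass circular-consensus
    structure of a short-insert library.  ``long_library`` switches to
    multi-kilobase inserts with 1-2 passes for phasing work.
    """

    seed: int = 0
    reference_length: int = 20_000
    motif: MotifSpec = field(default_factory=lambda: MotifSpec("GATC", 1))
    n_molecules: int = 100
    insert_mean: float = 250.0
    insert_sd: float = 25.0
    min_insert: int = 60
    read_length: int = 8_000
    adapter_len: int = 50
    context_sd: float = 0.4
    noise_sd: float = 1.2
    molecule_offset_sd: float = 0.3
    delta: float = 2.0
    regime: str = "constitutive"
    f_active: float = 1.0
    p_site: float = 1.0
    methylate_strands: str = "both"  # both | forward | reverse
    error_rate: float = 0.08
    sample_type: str = "native"
    context_seed: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if not 0.0 <= self.f_active <= 1.0 or not 0.0 <= self.p_site <= 1.0:
            raise ValueError("f_active and p_site must be fractions in [0, 1]")
        if self.methylate_strands not in ("both", "forward", "reverse"):
            raise ValueError("methylate_strands must be both|forward|reverse")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.min_insert > self.reference_length:
            raise ValueError("min_insert exceeds the reference length")

    @property
    def effective_context_seed(self) -> int:
        return self.seed if self.context_seed is None else self.context_seed

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def long_library(cls, **changes) -> "SimConfig":
        """Long-insert preset: multi-kilobase contiguous reads, 1-2 passes."""
        base = dict(insert_mean=5_000.0, insert_sd=800.0, reference_length=20_000)
        base.update(changes)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["motif"] = {
            "iupac": self.motif.iupac,
            "modified_index": self.motif.modified_index,
            "name": self.motif.name,
        }
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        m = data.pop("motif")
        motif = MotifSpec(m["iupac"], m["modified_index"], name=m.get("name", ""))
        return cls(motif=motif, **data)


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``molecules``: one row per molecule (regime label and whether its MTase
    was active).  ``sites``: one row per covered (molecule, strand, site)
    with its methylated flag.
    """

    molecules: pd.DataFrame
    sites: pd.DataFrame

    def methylated_site_fraction(self) -> float:
        if self.sites.empty:
            return 0.0
        return float(self.sites["methylated"].mean())


def simulate_reference(length: int, seed: int = 0) -> str:
    """Uniform random A/C/G/T sequence, deterministic per seed."""
    if length == 0:
        return ""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    return rng.choice(_BASES, size=length).tobytes().decode()


def _context_offsets(length: int, sd: float, context_seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([context_seed, 101]))
    return rng.normal(0.0, sd, size=(2, length))


def _site_positions(reference: str, motif: MotifSpec) -> dict[int, np.ndarray]:
    sites = find_motif_sites(reference, motif)
    return {
        s: np.array(sorted(x.ref_pos for x in sites if x.strand == s), dtype=np.int64)
        for s in (FORWARD, REVERSE)
    }


def simulate_dataset(
    cfg: SimConfig, reference: str | None = None
) -> tuple[KineticsDataset, TruthTable]:
    """Generate one aligned-kinetics dataset plus its ground truth."""
    if reference is None:
        reference = simulate_reference(cfg.reference_length, cfg.effective_context_seed)
    L = len(reference)
    if cfg.min_insert > L:
        raise ValueError("insert length cannot exceed the reference")
    ref_arr = np.frombuffer(reference.upper().encode(), dtype="S1")
    site_pos = _site_positions(reference, cfg.motif)
    wga = cfg.sample_type.lower() == "wga"
    delta = 0.0 if wga else cfg.delta
    if not wga and delta != 0.0 and all(len(v) == 0 for v in site_pos.values()):
        raise ValueError(
            f"reference contains no {cfg.motif.name} site; cannot apply a "
            "methylation regime"
        )
    ctx = _context_offsets(L, cfg.context_sd, cfg.effective_context_seed)
    role = _ROLE["wga" if wga else "native"]
    rng_struct = np.random.default_rng(np.random.SeedSequence([cfg.seed, role, 1]))
    rng_noise = np.random.default_rng(np.random.SeedSequence([cfg.seed, role, 2]))
    rng_err = np.random.default_rng(np.random.SeedSequence([cfg.seed, role, 3]))

    strand_on = {
        FORWARD: cfg.methylate_strands in ("both", "forward"),
        REVERSE: cfg.methylate_strands in ("both", "reverse"),
    }

    subreads: list[SubreadRecord] = []
    mol_rows = {"molecule_id": [], "regime": [], "methylated": []}
    site_rows = {"molecule_id": [], "strand": [], "ref_pos": [], "methylated": []}

    for m in range(cfg.n_molecules):
        mol_id = f"mol{m:06d}"
        ins_len = int(
            np.clip(round(rng_struct.normal(cfg.insert_mean, cfg.insert_sd)),
                    cfg.min_insert, L)
        )
        start = int(rng_struct.integers(0, L - ins_len + 1))
        end = start + ins_len
        n_pass = max(1, cfg.read_length // (ins_len + 2 * cfg.adapter_len))
        first_strand = int(rng_struct.integers(0, 2))
        mol_off = rng_struct.normal(0.0, cfg.molecule_offset_sd)

        if wga:
            active = False
        elif cfg.regime == "phase_variable":
            active = bool(rng_struct.random() < cfg.f_active)
        else:
            active = True
        mol_rows["molecule_id"].append(mol_id)
        mol_rows["regime"].append("wga" if wga else cfg.regime)
        mol_rows["methylated"].append(active)

        meth = {s: np.zeros(ins_len, dtype=bool) for s in (FORWARD, REVERSE)}
        for s in (FORWARD, REVERSE):
            pos = site_pos[s]
            covered = pos[(pos >= start) & (pos < end)]
            if covered.size == 0:
                continue
            if wga or not active or not strand_on[s]:
                flags = np.zeros(covered.size, dtype=bool)
            elif cfg.regime == "stochastic":
                flags = rng_struct.random(covered.size) < cfg.p_site
            else:
                flags = np.ones(covered.size, dtype=bool)
            meth[s][covered - start] = flags
            site_rows["molecule_id"].extend([mol_id] * covered.size)
            site_rows["strand"].extend([s] * covered.size)
            site_rows["ref_pos"].extend(covered.tolist())
            site_rows["methylated"].extend(flags.tolist())

        noise = rng_noise.normal(0.0, cfg.noise_sd, size=(n_pass, ins_len))
        for p in range(n_pass):
            s = (first_strand + p) % 2
            if s == FORWARD:
                positions = np.arange(start, end, dtype=np.int64)
            else:
                positions = np.arange(end - 1, start - 1, -1, dtype=np.int64)
            rel = positions - start
            log_ipd = ctx[s, positions] + mol_off + delta * meth[s][rel] + noise[p]
            ipd = np.exp(log_ipd)
            ops = np.full(ins_len, b"M", dtype="S1")
            read_b = ref_arr[positions].copy()
            ref_b = ref_arr[positions].copy()

            if cfg.error_rate > 0.0:
                err_idx = np.flatnonzero(rng_err.random(ins_len) < cfg.error_rate)
                etype = rng_err.integers(0, 3, size=err_idx.size)
                sub_idx = err_idx[etype == 0]
                if sub_idx.size:
                    shift = rng_err.integers(1, 4, size=sub_idx.size)
                    cur = np.searchsorted(_BASES, read_b[sub_idx])
                    read_b[sub_idx] = _BASES[(cur + shift) % 4]
                    ops[sub_idx] = b"X"
                del_idx = err_idx[etype == 2]
                if del_idx.size:
                    ops[del_idx] = b"D"
                    read_b[del_idx] = b"."
                    ipd = ipd.copy()
                    ipd[del_idx] = np.nan
                ins_idx = err_idx[etype == 1]
                if ins_idx.size:
                    ins_b = _BASES[rng_err.integers(0, 4, size=ins_idx.size)]
                    ins_ipd = np.exp(
                        mol_off + rng_err.normal(0.0, cfg.noise_sd, size=ins_idx.size)
                    )
                    at = ins_idx + 1
                    positions = np.insert(positions, at, NULL_POS)
                    ops = np.insert(ops, at, b"I")
                    read_b = np.insert(read_b, at, ins_b)
                    ref_b = np.insert(ref_b, at, b".")
                    ipd = np.insert(ipd, at, ins_ipd)

            n_match = int(np.count_nonzero(ops == b"M"))
            n_emitted = int(np.count_nonzero(ops != b"D"))
            accuracy = n_match / n_emitted if n_emitted else 0.0
            subreads.append(
                SubreadRecord(
                    molecule_id=mol_id,
                    subread_index=p,
                    strand=s,
                    mapqv=254,
                    accuracy=accuracy,
                    ref_pos=positions,
                    op=ops,
                    read_base=read_b,
                    ref_base=ref_b,
                    ipd=ipd,
                )
            )

    ds = KineticsDataset(
        subreads=subreads,
        reference_id="simref",
        reference_length=L,
        sample_type="wga" if wga else "native",
        ipd_unit="seconds",
        provenance={"simulated": True, "seed": cfg.seed, "regime": cfg.regime},
    )
    truth = TruthTable(
        molecules=pd.DataFrame(mol_rows),
        sites=pd.DataFrame(
            {
                "molecule_id": site_rows["molecule_id"],
                "strand": np.array(site_rows["strand"], dtype=np.int8),
                "ref_pos": np.array(site_rows["ref_pos"], dtype=np.int64),
                "methylated": np.array(site_rows["methylated"], dtype=bool),
            }
        ),
    )
    return ds, truth


def simulate_pair(
    cfg: SimConfig, n_wga: int | None = None, reference: str | None = None
) -> tuple[KineticsDataset, KineticsDataset, str, TruthTable]:
    """Generate a native dataset and its WGA twin on one shared reference.

    The twins share the per-position context offsets (same context seed)
    but draw independent noise, molecules and errors, so the WGA
    subtraction removes context bias exactly as it does for real paired
    samples.
    """
    if cfg.sample_type.lower() != "native":
        raise ValueError("simulate_pair expects a native-sample config")
    if reference is None:
        reference = simulate_reference(cfg.reference_length, cfg.effective_context_seed)
    native_ds, truth = simulate_dataset(cfg, reference)
    wga_cfg = cfg.replace(
        sample_type="wga",
        n_molecules=n_wga if n_wga is not None else cfg.n_molecules,
        context_seed=cfg.effective_context_seed,
    )
    wga_ds, _ = simulate_dataset(wga_cfg, reference)
    return native_ds, wga_ds, reference, truth


def config_hash(cfg: SimConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def write_fixture_pair(
    cfg: SimConfig, out_dir, n_wga: int | None = None, write_bam: bool = False
) -> dict[str, str]:
    """Emit a native/WGA fixture pair with reference, truth and manifest.

    Outputs are deterministic: the same config and seed produce
    byte-identical files.  Returns a name -> path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    native_ds, wga_ds, reference, truth = simulate_pair(cfg, n_wga=n_wga)
    paths = {
        "native": out / "native.tsv",
        "wga": out / "wga.tsv",
        "reference": out / "reference.fasta",
        "truth_sites": out / "truth_sites.tsv",
        "truth_molecules": out / "truth_molecules.tsv",
        "manifest": out / "manifest.json",
    }
    kio.write_kinetics_tsv(paths["native"], native_ds)
    kio.write_kinetics_tsv(paths["wga"], wga_ds)
    with open(paths["reference"], "w", encoding="utf-8") as fh:
        fh.write(">simref\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i : i + 70] + "\n")
    truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    truth.molecules.to_csv(paths["truth_molecules"], sep="\t", index=False)
    if write_bam:
        paths["native_bam"] = out / "native.bam"
        paths["wga_bam"] = out / "wga.bam"
        kio.write_kinetics_bam(paths["native_bam"], native_ds)
        kio.write_kinetics_bam(paths["wga_bam"], wga_ds)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": config_hash(cfg),
        "n_wga": n_wga if n_wga is not None else cfg.n_molecules,
        "files": {k: str(v.name) for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("fixture pair written to %s", out)
    return {k: str(v) for k, v in paths.items()}
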
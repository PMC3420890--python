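"""Shared plumbing for the numbered analysis drivers.

The drivers operate on one synthetic sample of the default reporter-vector
scenario (20,000 reads, seed 1) written by 01_simulate.py into scratch/sim.
Raw data live under scratch/ (regenerable, not part of the deliverable);
small derived tables go to results/.
"""

from pathlib import Path

from plasmidseq.model import AnalysisConfig, load_reference
from plasmidseq.pipeline import run
from plasmidseq.readprep import read_fastq
from plasmidseq.simulate import DEFAULT_ADAPTER, pegfp_like

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

SEED = 1
TOTAL_READS = 20_000


def sim_config():
    return pegfp_like(seed=SEED, total_reads=TOTAL_READS)


def load_sample():
    if not (SIM_DIR / "reads.fastq").exists():
        raise SystemExit("no simulated sample found; run analysis/01_simulate.py first")
    ref = load_reference(SIM_DIR / "reference.fasta", SIM_DIR / "annotation.tsv")
    reads = list(read_fastq(SIM_DIR / "reads.fastq"))
    return ref, reads


def run_pipeline_on_sample():
    ref, reads = load_sample()
    cfg = AnalysisConfig(adapter=DEFAULT_ADAPTER)
    return run(reads, ref, cfg)
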
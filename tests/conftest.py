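import numpy as np
import pytest

from tstructseq import reactivity, readproc, simdata
from tstructseq.engines import BuiltinEngine


@pytest.fixture(scope="session")
def builtin_engine():
    return BuiltinEngine()


@pytest.fixture(scope="session")
def sim_experiment():
    """A full synthetic probing experiment at the default study conditions."""
    cfg = simdata.SimConfig(seed=11)
    truth, treated, untreated = simdata.run_experiment(cfg)
    return cfg, truth, treated, untreated


def profiles_from_reads(truth, treated, untreated):
    """readproc + reactivity on simulated reads -> per-primer and combined profiles."""
    per_primer = []
    for entry in truth.panel:
        tc = readproc.accumulate_counts(
            [r for r in treated if r.primer == entry.name], entry, "treated",
            truth.transcript.length, transcript=truth.transcript.name)
        uc = readproc.accumulate_counts(
            [r for r in untreated if r.primer == entry.name], entry, "untreated",
            truth.transcript.length, transcript=truth.transcript.name)
        per_primer.append(reactivity.compute_pdms(tc, uc))
    combined = reactivity.combine_primers(per_primer, truth.panel)
    return per_primer, reactivity.classify_reactivity(combined)


@pytest.fixture(scope="session")
def sim_profiles(sim_experiment):
    cfg, truth, treated, untreated = sim_experiment
    per_primer, combined = profiles_from_reads(truth, treated, untreated)
    return truth, per_primer, combined


def make_counts(transcript_length, condition="treated", primer="P", n=None, r=None,
                transcript="tx"):
    tc = readproc.TerminationCounts(transcript=transcript, condition=condition,
                                    primer=primer, length=transcript_length)
    for i, v in (n or {}).items():
        tc.n[i] = v
    for i, v in (r or {}).items():
        tc.r[i] = v
    return tc


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
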
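from types import SimpleNamespace

import pytest

from scires.genotyping import CallingParams, call_sample
from scires.res_detection import run_pipeline
from scires.synthetic_data import SimConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """The default simulated study: 6 oocytes + PB1s + liver, seed 42."""
    return generate_bundle(SimConfig())


@pytest.fixture(scope="session")
def default_analysis(default_bundle):
    """Full analysis of the default bundle: consensus calls everywhere
    plus the editing-detection pipeline result."""
    bundle = default_bundle
    cfg = bundle.config
    params = CallingParams()
    dna_calls = {name: call_sample(sp.iter_columns(), params)
                 for name, sp in bundle.dna_pileups.items()}
    rna_calls = {name: call_sample(r.pileup.iter_columns(), params)
                 for name, r in bundle.rna.items()}
    oocyte_calls = {n: dna_calls[n] for n in cfg.oocyte_names}
    pb1_calls = {cfg.oocyte_names[i]: dna_calls[cfg.pb1_names[i]]
                 for i in range(cfg.n_oocytes)}
    result = run_pipeline(oocyte_calls, rna_calls, dna_calls["liver"],
                          bundle.transcripts, min_depth=8)
    return SimpleNamespace(bundle=bundle, config=cfg, params=params,
                           dna_calls=dna_calls, rna_calls=rna_calls,
                           oocyte_calls=oocyte_calls, pb1_calls=pb1_calls,
                           liver_calls=dna_calls["liver"], result=result)
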
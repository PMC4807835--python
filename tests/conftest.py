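import numpy as np
import pandas as pd


def toy_expression(values: np.ndarray, cell_type: str = "CD4", disease=None,
                   batch=None, seed: int = 0):
    """Wrap a samples x probesets array into an ExpressionMatrix."""
    from mceqtl.ioformats import ExpressionMatrix

    rng = np.random.default_rng(seed)
    n, m = values.shape
    samples = [f"S{i}" for i in range(n)]
    if disease is None:
        disease = rng.integers(0, 2, size=n)
    if batch is None:
        batch = np.where(np.arange(n) < n // 2, "B1", "B2")
    cov = pd.DataFrame(
        {
            "individual_id": [f"I{i}" for i in range(n)],
            "cell_type": cell_type,
            "disease": disease,
            "batch": batch,
            "sex": "F",
            "timepoint": "t0",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    vals = pd.DataFrame(values, index=cov.index,
                        columns=[f"PS{j:03d}" for j in range(m)])
    return ExpressionMatrix(vals, cell_type, cov)
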
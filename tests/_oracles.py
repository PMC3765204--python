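"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: exact integer
arithmetic for the hypergeometric enumeration, and direct conditional
likelihood evaluation for the odds-ratio estimate.
"""

import math

# mirror of the implementation's tie convention (relative tolerance 1e-7),
# expressed in exact integer arithmetic: w <= w_obs * (1 + 1e-7)
TIE_NUM = 10**7


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with integer weights."""
    m_a, m_b, k = a + b, c + d, a + c
    if m_a + m_b == 0:
        return float("nan")
    lo, hi = max(0, k - m_b), min(m_a, k)
    weights = [math.comb(m_a, x) * math.comb(m_b, k - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    kept = sum(w for w in weights if w * TIE_NUM <= w_obs * TIE_NUM + w_obs)
    return kept / math.comb(m_a + m_b, k)


def conditional_log_likelihood(a: int, b: int, c: int, d: int, psi: float) -> float:
    """Log conditional likelihood of the first cell given all margins."""
    m_a, m_b, k = a + b, c + d, a + c
    lo, hi = max(0, k - m_b), min(m_a, k)
    log_terms = [
        math.log(math.comb(m_a, x)) + math.log(math.comb(m_b, k - x)) + x * math.log(psi)
        for x in range(lo, hi + 1)
    ]
    peak = max(log_terms)
    log_norm = peak + math.log(sum(math.exp(t - peak) for t in log_terms))
    return log_terms[a - lo] - log_norm


def is_conditional_mle(a: int, b: int, c: int, d: int, psi: float, rel: float = 1e-4) -> bool:
    """Check that psi locally maximizes the conditional likelihood."""
    ll = conditional_log_likelihood(a, b, c, d, psi)
    return ll >= conditional_log_likelihood(a, b, c, d, psi * (1 + rel)) and ll >= (
        conditional_log_likelihood(a, b, c, d, psi * (1 - rel))
    )
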
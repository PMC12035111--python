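# Registry of simulation data-generating mechanisms.
# Gamma laws are parameterized as shape k / scale theta.  Mixed mechanisms
# draw the group from a single normal whose mean and variance combine the
# component parameters as pi*mu_1 + (1-pi)*mu_2 and
# pi^2*sd_1^2 + (1-pi)^2*sd_2^2 (the literal combined-moment reading; set
# mixture_literal=false at generation time for a genuine 2-component draw).
BN_equal:
  low:    {mu0: 0.0, mu1: 0.2, sigma0: 1.0, sigma1: 1.0}
  medium: {mu0: 0.0, mu1: 1.0, sigma0: 1.0, sigma1: 1.0}
  high:   {mu0: 0.0, mu1: 2.5, sigma0: 1.0, sigma1: 1.0}
BN_unequal:
  low:    {mu0: 0.0, mu1: 0.2, sigma0: 1.2, sigma1: 0.8}
  medium: {mu0: 0.0, mu1: 1.0, sigma0: 1.2, sigma1: 0.5}
  high:   {mu0: 1.0, mu1: 2.9, sigma0: 0.5, sigma1: 1.2}
Skewed_I:  # biomarker = (normal draw)^2: Y^(1/2) ~ N(mu, sigma^2)
  low:    {mu0: 0.0, mu1: 0.2, sigma0: 1.2, sigma1: 1.0}
  medium: {mu0: 0.0, mu1: 1.0, sigma0: 1.0, sigma1: 0.7}
  high:   {mu0: 1.0, mu1: 2.5, sigma0: 1.0, sigma1: 0.5}
Skewed_II:  # log-normal: log(Y) ~ N(mu, sigma^2)
  low:    {mu0: 0.0, mu1: 0.2, sigma0: 1.0, sigma1: 1.0}
  medium: {mu0: 0.0, mu1: 1.0, sigma0: 1.0, sigma1: 0.7}
  high:   {mu0: 1.0, mu1: 2.5, sigma0: 1.0, sigma1: 0.5}
Skewed_III:  # gamma, shared shape k
  low:    {k: 0.5, theta0: 0.1, theta1: 0.15}
  medium: {k: 0.5, theta0: 0.1, theta1: 0.6}
  high:   {k: 0.5, theta0: 0.1, theta1: 7.0}
Mixed_I:  # healthy plain normal; diseased combined normal
  low:    {mu0: 0.0, sigma0: 1.0, pi1: 0.5, mu11: 0.0, sigma11: 1.0, mu12: 1.0, sigma12: 5.0}
  medium: {mu0: 0.0, sigma0: 1.0, pi1: 0.5, mu11: 0.0, sigma11: 1.0, mu12: 4.0, sigma12: 5.0}
  high:   {mu0: 0.0, sigma0: 1.0, pi1: 0.5, mu11: 0.0, sigma11: 1.0, mu12: 8.0, sigma12: 5.0}
Mixed_II:  # both groups combined normals
  low:    {pi0: 0.5, mu01: 0.0, sigma01: 1.0, mu02: 1.0, sigma02: 2.0,
           pi1: 0.4, mu11: 0.0, sigma11: 1.0, mu12: 1.5, sigma12: 2.5}
  medium: {pi0: 0.5, mu01: 0.0, sigma01: 1.0, mu02: 1.0, sigma02: 5.0,
           pi1: 0.4, mu11: 0.0, sigma11: 1.0, mu12: 2.5, sigma12: 2.5}
  high:   {pi0: 0.5, mu01: 0.0, sigma01: 1.0, mu02: 1.0, sigma02: 5.0,
           pi1: 0.4, mu11: 0.0, sigma11: 1.0, mu12: 5.0, sigma12: 2.5}
# Covariate mechanisms: X0, X1 ~ Uniform(-0.5, 1.5) independently per group.
Cov_BN:
  not_applicable: {b00: 1.0, b01: 1.0, sigma0: 1.0, b10: 1.5, b11: 2.0, sigma1: 1.0}
Cov_Skewed:  # gamma with covariate-dependent scale
  not_applicable: {k: 2.0, b00: 3.0, b01: 0.1, b10: 5.0, b11: 9.0}
Cov_Mixed:  # healthy normal regression; diseased combined normal regression
  not_applicable: {a00: 0.0, a01: 1.0, sigma0: 1.0, pi1: 0.5,
                   a101: 0.0, a111: 1.0, a102: 1.0, a112: 5.0, sigma1: 1.5}
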
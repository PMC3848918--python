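# Default parameter search ranges for the built-in models.
#
# These are starting points for typical lab data (optical-density growth
# curves in hours; tumor size series in days) — real analyses should narrow
# them around the data at hand.  lower/upper are the box constraints handed
# to the optimizer; is_initial_condition marks parameters describing the
# state at the first observation, whose start value is taken from the data.

gompertz:
  display_name: "Gompertz (modified, Zwietering)"
  equation_text: "y(t) = A*exp(-exp((mu_max*e/A)*(lambda - t) + 1))"
  parameters:
    A:        {lower: 0.01,  upper: 100.0, default_guess: 1.0}
    mu_max:   {lower: 0.001, upper: 10.0,  default_guess: 0.5}
    lambda_:  {lower: -10.0, upper: 100.0, default_guess: 2.0}

logistic:
  display_name: "Logistic (Zwietering)"
  equation_text: "y(t) = A / (1 + exp(4*mu_max*(lambda - t)/A + 2))"
  parameters:
    A:        {lower: 0.01,  upper: 100.0, default_guess: 1.0}
    mu_max:   {lower: 0.001, upper: 10.0,  default_guess: 0.5}
    lambda_:  {lower: -10.0, upper: 100.0, default_guess: 2.0}

richards:
  display_name: "Richards (Zwietering)"
  equation_text: "y(t) = A*(1 + v*exp(1+v)*exp((mu_max/A)*(1+v)^(1+1/v)*(lambda - t)))^(-1/v)"
  parameters:
    A:        {lower: 0.01,  upper: 100.0, default_guess: 1.0}
    mu_max:   {lower: 0.001, upper: 10.0,  default_guess: 0.5}
    lambda_:  {lower: -10.0, upper: 100.0, default_guess: 2.0}
    v:        {lower: 0.05,  upper: 20.0,  default_guess: 1.0}

baranyi:
  display_name: "Baranyi-Roberts (adjustment scaled by 1/mu_max)"
  equation_text: "y(t) = y0 + mu_max*A(t) - (1/m)*ln(1 + (exp(m*mu_max*A(t)) - 1)/exp(m*(y_max - y0))), A(t) = t + (1/mu_max)*ln(exp(-v*t) + exp(-h0) - exp(-v*t - h0))"
  parameters:
    y0:       {lower: -5.0,  upper: 10.0,  is_initial_condition: true, default_guess: 0.1}
    y_max:    {lower: 0.5,   upper: 20.0,  default_guess: 9.0}
    mu_max:   {lower: 0.01,  upper: 10.0,  default_guess: 0.5}
    v_rate:   {lower: 0.01,  upper: 10.0,  default_guess: 0.5}
    h0:       {lower: 0.0,   upper: 20.0,  default_guess: 2.0}
    m_curv:   {lower: 0.1,   upper: 10.0,  default_guess: 1.0}

baranyi_classic:
  display_name: "Baranyi-Roberts (adjustment scaled by 1/v)"
  equation_text: "y(t) = y0 + mu_max*A(t) - (1/m)*ln(1 + (exp(m*mu_max*A(t)) - 1)/exp(m*(y_max - y0))), A(t) = t + (1/v)*ln(exp(-v*t) + exp(-h0) - exp(-v*t - h0))"
  parameters:
    y0:       {lower: -5.0,  upper: 10.0,  is_initial_condition: true, default_guess: 0.1}
    y_max:    {lower: 0.5,   upper: 20.0,  default_guess: 9.0}
    mu_max:   {lower: 0.01,  upper: 10.0,  default_guess: 0.5}
    v_rate:   {lower: 0.01,  upper: 10.0,  default_guess: 0.5}
    h0:       {lower: 0.0,   upper: 20.0,  default_guess: 2.0}
    m_curv:   {lower: 0.1,   upper: 10.0,  default_guess: 1.0}

h3:
  display_name: "Hyperbolastic growth type III (H3)"
  equation_text: "P(t) = M - alpha*exp(-delta*t^gamma - arcsinh(theta*t)), alpha = (M - P0)*exp(delta*t0^gamma + arcsinh(theta*t0))"
  parameters:
    M:        {lower: 0.1,   upper: 100.0, default_guess: 10.0}
    delta:    {lower: 1.0e-12, upper: 0.1, default_guess: 1.0e-6}
    gamma:    {lower: 0.2,   upper: 10.0,  default_guess: 2.0}
    theta:    {lower: 0.0,   upper: 1.0,   default_guess: 0.01}
    P0:       {lower: 0.001, upper: 50.0,  is_initial_condition: true, default_guess: 0.5}
    t0:       {lower: 0.0,   upper: 100.0, is_initial_condition: true, default_guess: 0.0}

lcf:
  display_name: "Live Cell Fraction (spheroid radius ODE)"
  equation_text: "dr/dt = r(t)/3 * ((alpha + delta)*3*lambda/(3*lambda + r(t)) - delta)"
  parameters:
    alpha:        {lower: 0.001, upper: 5.0,   default_guess: 0.2}
    delta:        {lower: 0.001, upper: 5.0,   default_guess: 0.05}
    lambda_depth: {lower: 0.01,  upper: 100.0, default_guess: 1.0}
    r0:           {lower: 0.001, upper: 50.0,  is_initial_condition: true, default_guess: 1.0}

poly1:
  display_name: "First-order polynomial"
  equation_text: "y(t) = c0 + c1*t"
  parameters:
    c0: {lower: -1.0e6, upper: 1.0e6, default_guess: 0.0}
    c1: {lower: -1.0e6, upper: 1.0e6, default_guess: 0.0}

poly2:
  display_name: "Second-order polynomial"
  equation_text: "y(t) = c0 + c1*t + c2*t^2"
  parameters:
    c0: {lower: -1.0e6, upper: 1.0e6, default_guess: 0.0}
    c1: {lower: -1.0e6, upper: 1.0e6, default_guess: 0.0}
    c2: {lower: -1.0e6, upper: 1.0e6, default_guess: 0.0}

exp_decay:
  display_name: "Exponential decay"
  equation_text: "y(t) = c + (y0 - c)*exp(-k*t)"
  parameters:
    y0: {lower: -100.0, upper: 100.0, is_initial_condition: true, default_guess: 1.0}
    k:  {lower: 1.0e-4, upper: 10.0,  default_guess: 0.5}
    c:  {lower: -100.0, upper: 100.0, default_guess: 0.0}
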
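# Reference estimate of the transmigration model parameters (a.u. / hours).
t1 = 3.5000
k_e0 = 11.2464
k_k1 = 0.1017
beta = 0.0134
k_w0 = 1.4037
k_k2 = 0.0937
k_rhch = 0.3704
k_hs = 0.0002
k_hchrb = 0.9997
k_hchrt = 0.0757
k_hrs = 0.7232
k_hcsb = 1.9997
k_hcst = 0.2668
k_ss = 0.1024
k_pmnipb = 0.2226
k_pmnipt = 2.0000
k_pmnps = 0.1003
k_mpipb = 0.0001
k_mpipt = 1.0108
k_mpps = 0.1961
k_pmns = 0.0582
k_mps = 0.0307
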
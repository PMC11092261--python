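seq_0001	Phylum1;Species1;
seq_0002	Phylum1;Species1;
seq_0003	Phylum1;Species1;
seq_0004	Phylum1;Species1;
seq_0005	Phylum1;Species1;
seq_0006	Phylum1;Species2;
seq_0007	Phylum1;Species2;
seq_0008	Phylum1;Species2;
seq_0009	Phylum1;Species2;
seq_0010	Phylum1;Species2;
seq_0011	Phylum1;Species3;
seq_0012	Phylum1;Species3;
seq_0013	Phylum1;Species3;
seq_0014	Phylum1;Species3;
seq_0015	Phylum1;Species3;
seq_0016	Phylum2;Species4;
seq_0017	Phylum2;Species4;
seq_0018	Phylum2;Species4;
seq_0019	Phylum2;Species4;
seq_0020	Phylum2;Species4;
seq_0021	Phylum2;Species5;
seq_0022	Phylum2;Species5;
seq_0023	Phylum2;Species5;
seq_0024	Phylum2;Species5;
seq_0025	Phylum2;Species5;
seq_0026	Phylum2;Species6;
seq_0027	Phylum2;Species6;
seq_0028	Phylum2;Species6;
seq_0029	Phylum2;Species6;
seq_0030	Phylum2;Species6;
seq_0031	Phylum3;Species7;
seq_0032	Phylum3;Species7;
seq_0033	Phylum3;Species7;
seq_0034	Phylum3;Species7;
seq_0035	Phylum3;Species7;
seq_0036	Phylum3;Species8;
seq_0037	Phylum3;Species8;
seq_0038	Phylum3;Species8;
seq_0039	Phylum3;Species8;
seq_0040	Phylum3;Species8;
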
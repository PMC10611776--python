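species,parent_id,start,end,sequence,missed_cleavages,label,precursor_charge,rt_min,product_ions
macaque,mFXN-M,81,97,SGTLGHPGSLDDTTYER,0,light,3,3.03,y14^2;y5^1;y3^1
human,hFXN-M,81,97,SGTLGHPGSLDETTYER,0,light,3,3.07,y14^2;y5^1;y3^1
human,hFXN-M,81,97,SGTLGHPGSLDETTYER,0,heavy,3,3.07,y14^2;y5^1;y4^1
both,hFXN-M,153,165,QIWLSSPSSGPKR,1,light,2,4.10,y10^1;y9^1;y8^1
both,hFXN-M,153,165,QIWLSSPSSGPKR,1,heavy,2,4.10,y10^1;y9^1;y8^1
both,hFXN-M,136,147,LGGDLGTYVINK,0,light,2,5.05,y8^1;y7^1;y2^1
both,hFXN-M,136,147,LGGDLGTYVINK,0,heavy,2,5.05,y8^1;y7^1;y2^1
both,hFXN-M,198,208,LDLSSLAYSGK,0,light,2,5.90,y8^1;y6^1;y5^1
both,hFXN-M,198,208,LDLSSLAYSGK,0,heavy,2,5.90,y8^1;y6^1;y5^1
macaque,mFXN-M,172,192,NWVYSHDGVSLHELLGAELTK,0,light,4,6.46,y19^3;y8^1;y7^1
human,hFXN-M,172,192,NWVYSHDGVSLHELLAAELTK,0,light,4,6.56,y19^3;y8^1;y7^1
human,hFXN-M,172,192,NWVYSHDGVSLHELLAAELTK,0,heavy,4,6.56,y19^3;y8^1;y7^1
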